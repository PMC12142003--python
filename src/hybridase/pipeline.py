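"""End-to-end orchestration: config file in, report bundle out.

Stages run in a fixed order — assemble/quantify, the seven differential
contrasts, the inheritance / regulatory / imprinting classifiers, the
enrichment analyses, then the optional read-ambiguity, mitochondria and
TE tracks — each consuming only primary inputs or files written by earlier
stages.  A run is deterministic: the same config produces a byte-identical
bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

import hybridase
from hybridase import enrichment, orthology, quantify, tracks
from hybridase.model import HYBRIDS, HybridAseModel, Thresholds

log = logging.getLogger("hybridase")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths, thresholds and run parameters for one analysis.

    Optional inputs (``gene_sets``, ``mito_genes``, ``mito_hits``,
    ``te_counts``, ``read_records``) switch their stage on when present.
    """

    counts: str
    sample_sheet: str
    ortholog_map: str
    outdir: str
    chromosomes: str | None = None
    gene_sets: str | None = None
    mito_genes: str | None = None
    mito_hits: str | None = None
    te_counts: str | None = None
    read_records: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        known = {f.name for f in fields(cls)} - {"thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=th, **raw)

    def require_paths(self) -> None:
        for name in ("counts", "sample_sheet", "ortholog_map"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} not found")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns a mapping of artifact name -> path.

    Emits per-stage TSVs, ``summary.json`` and ``run.log`` under
    ``config.outdir``.  Any stage failure raises :class:`StageError` naming
    the stage.
    """
    config.require_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    note(f"hybridase {hybridase.__version__}")
    note(f"seed {config.seed}")
    for name, value in vars(config.thresholds).items():
        note(f"threshold {name} = {value}")

    paths: dict[str, Path] = {}
    stage = "quantify"
    try:
        model = HybridAseModel.from_tables(
            config.counts,
            config.sample_sheet,
            config.ortholog_map,
            chromosomes_path=config.chromosomes,
            thresholds=config.thresholds,
        )
        note(f"assembled {model.table.counts.shape[0]} ortholog pairs x "
             f"{model.table.counts.shape[1]} columns")

        stage = "fit"
        results = model.fit()
        note(f"{len(results.expressed)} pairs pass the expression filter")
        paths.update(results.save(outdir))

        stage = "enrichment"
        summary = results.to_summary_dict()
        if model.chromosomes is not None:
            chrom_tables = []
            for which in ("inheritance", "regulatory"):
                for hybrid in HYBRIDS:
                    tab = results.chromosome_enrichment(which, hybrid)
                    tab.insert(0, "analysis", which)
                    tab.insert(1, "hybrid", hybrid)
                    chrom_tables.append(tab)
            chrom_df = pd.concat(chrom_tables, ignore_index=True)
            p = outdir / "chromosome_enrichment.tsv"
            chrom_df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths["chromosome_enrichment"] = p
            summary["chromosome_flags"] = int(chrom_df["significant"].sum())
            note(f"{summary['chromosome_flags']} chromosome x category "
                 "cells flagged")

        if config.gene_sets:
            sets = enrichment.read_gmt(config.gene_sets)
            background = list(results.expressed)
            ora_tables = []
            venn = results.venn("inheritance")
            for cat in ("overdominant", "underdominant"):
                for part in ("shared", "bn_only", "nb_only"):
                    query = venn[cat][part]
                    if not query:
                        continue
                    tab = enrichment.overrepresentation(
                        query, sets, background
                    )
                    tab.insert(0, "query", f"{cat}_{part}")
                    ora_tables.append(tab)
            if ora_tables:
                ora = pd.concat(ora_tables, ignore_index=True)
                p = outdir / "gene_set_enrichment.tsv"
                ora.to_csv(p, sep="\t", index=False, float_format="%.6g")
                paths["gene_set_enrichment"] = p
        else:
            note("gene-set stage skipped (no gene_sets input)")

        stage = "ambiguity"
        if config.read_records:
            records = pd.read_csv(config.read_records, sep="\t")
            stats = quantify.mapping_ambiguity(records)
            amb = {
                "n_reads": stats.n_reads,
                "n_ambiguous": stats.n_ambiguous,
                "n_assigned_cbr": stats.n_assigned_cbr,
                "n_assigned_cni": stats.n_assigned_cni,
                "ambiguous_fraction": round(stats.ambiguous_fraction, 6),
            }
            p = outdir / "ambiguity.json"
            _json_dump(amb, p)
            paths["ambiguity"] = p
            summary["ambiguity"] = amb
        else:
            note("ambiguity stage skipped (no read_records input)")

        stage = "mito"
        if config.mito_genes:
            mito_ids = [
                line.strip()
                for line in Path(config.mito_genes).read_text().splitlines()
                if line.strip()
            ]
            counts = model.table.counts
            mito_libs = tracks.mito_library_sizes(counts, mito_ids)
            mito_cpm = quantify.cpm(
                counts.loc[counts.index.intersection(mito_ids)], mito_libs
            )
            p = outdir / "mito_cpm.tsv"
            mito_cpm.to_csv(p, sep="\t", float_format="%.6g")
            paths["mito_cpm"] = p
            if config.mito_hits:
                hits = orthology.read_hits(config.mito_hits)
                groups = orthology.group_one_to_n(hits)
                term_expr = tracks.mito_term_expression(counts, groups)
                p = outdir / "mito_term_expression.tsv"
                term_expr.to_csv(p, sep="\t", float_format="%.6g")
                paths["mito_terms"] = p
                summary["mito_terms"] = int(term_expr.shape[0])
        else:
            note("mito stage skipped (no mito_genes input)")

        stage = "te"
        if config.te_counts:
            te = pd.read_csv(config.te_counts, sep="\t", index_col=0)
            meta_cols = [c for c in ("species", "class") if c in te.columns]
            te_counts = te.drop(columns=meta_cols)
            te_libs = te_counts.sum(axis=0).astype(float)
            kept = tracks.te_filter(quantify.cpm(te_counts, te_libs))
            cols_bn = [c for c in te_counts.columns if c.startswith("BN")]
            cols_nb = [c for c in te_counts.columns if c.startswith("NB")]
            de = tracks.te_differential(
                te_counts.loc[kept],
                cols_bn,
                cols_nb,
                alpha=config.thresholds.alpha_raw,
                lfc_cut=config.thresholds.lfc_cut,
                library_sizes=te_libs,
            )
            p = outdir / "te_differential.tsv"
            de.to_csv(p, sep="\t", float_format="%.6g")
            paths["te_differential"] = p
            summary["te_families_kept"] = int(len(kept))
            summary["te_flagged"] = int((de["flag"] != "ns").sum())
            note(f"TE: {len(kept)} families kept, "
                 f"{summary['te_flagged']} flagged")
        else:
            note("TE stage skipped (no te_counts input)")

        stage = "report"
        p = outdir / "summary.json"
        _json_dump(summary, p)
        paths["summary"] = p
        note("pipeline complete")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        paths["run_log"] = outdir / "run.log"
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with the stage name
        raise StageError(stage, err) from err
    return paths
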