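"""Model/results facade over the full allele-specific expression analysis.

:class:`HybridAseModel` is built from an :class:`~hybridase.quantify.AlleleCountTable`
(or from the on-disk TSV bundle, or straight from a simulated experiment);
``fit()`` runs the expression filter, the seven differential contrasts and
the three classifiers, and returns a :class:`HybridAseResults` holding every
per-gene call together with summary tables, in the spirit of a statsmodels
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hybridase import detest, enrichment, imprinting, inheritance, quantify, regulatory
from hybridase.quantify import AlleleCountTable

HYBRIDS = ("BN", "NB")


@dataclass(frozen=True)
class Thresholds:
    """Every cutoff the analysis applies, in one place.

    ``alpha_fdr`` gates the inheritance and regulatory classifiers (BH FDR),
    ``alpha_raw`` the allele-contrast and TE flags (raw p); ``lfc_cut`` is
    the |log2 fold change| cutoff; ``reg_delta`` the |ratio_P - ratio_H|
    (log2) bound below which divergence counts as cis; ``imprint_cutoff``
    the allelic-fraction bound for imprinting; the filter keeps genes with
    CPM > ``filter_min_cpm`` in >= ``filter_min_columns`` columns; the
    chromosome enrichment flags cells with p < ``enrich_alpha`` and
    |log2 OR| > ``enrich_lor_cut``.
    """

    alpha_fdr: float = 0.05
    alpha_raw: float = 0.05
    lfc_cut: float = 1.0
    reg_delta: float = 1.8
    imprint_cutoff: float = 0.75
    imprint_min_cpm: float = 5.0
    filter_min_cpm: float = 2.0
    filter_min_columns: int = 4
    enrich_alpha: float = 0.01
    enrich_lor_cut: float = 0.4

    def __post_init__(self):
        for name in ("alpha_fdr", "alpha_raw", "imprint_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


class HybridAseModel:
    """Allele-specific expression model for one reciprocal-hybrid experiment.

    Parameters
    ----------
    table : AlleleCountTable
        Pair-level haplotype-resolved counts for the six expression groups.
    chromosomes : pandas.Series, optional
        pair id -> chromosome label, enabling chromosome enrichment.
    thresholds : Thresholds
        Classification cutoffs.
    dispersion : float, optional
        Fix the NB dispersion instead of estimating it per contrast.
    """

    def __init__(
        self,
        table: AlleleCountTable,
        chromosomes: pd.Series | None = None,
        thresholds: Thresholds = Thresholds(),
        dispersion: float | None = None,
    ):
        self.table = table
        self.chromosomes = chromosomes
        self.thresholds = thresholds
        self.dispersion = dispersion

    @classmethod
    def from_tables(
        cls,
        counts_path,
        sample_sheet_path,
        ortholog_map_path,
        chromosomes_path=None,
        **kwargs,
    ) -> "HybridAseModel":
        """Build the model from the on-disk TSV bundle."""
        gene_counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_path, sep="\t")
        omap = pd.read_csv(ortholog_map_path, sep="\t")
        table = quantify.assemble_groups(gene_counts, sheet, omap)
        chrom = None
        if chromosomes_path is not None:
            chrom = pd.read_csv(
                chromosomes_path, sep="\t", index_col=0
            ).iloc[:, 0]
        elif "chromosome" in omap.columns:
            chrom = omap.set_index("pair_id")["chromosome"]
        return cls(table, chromosomes=chrom, **kwargs)

    @classmethod
    def from_simulation(cls, experiment, **kwargs) -> "HybridAseModel":
        """Build the model from a :class:`~hybridase.simulate.SimulatedExperiment`."""
        table = experiment.to_allele_table()
        chrom = experiment.truth["chromosome"]
        return cls(table, chromosomes=chrom, **kwargs)

    # -- contrasts -------------------------------------------------------

    def _contrast_frames(self, expressed: pd.Index):
        """Per-contrast (counts, library_sizes, Contrast) triples."""
        t = self.table
        sub = t.subset(expressed)
        frames = {}

        cbr_cols = t.columns_for("Cbr")
        cni_cols = t.columns_for("Cni")
        parental = pd.concat(
            [sub.counts[cbr_cols], sub.counts[cni_cols]], axis=1
        )
        libs = t.library_sizes[cbr_cols + cni_cols]
        frames["parental"] = (
            parental,
            libs,
            detest.Contrast(tuple(cbr_cols), tuple(cni_cols), "Cbr vs Cni"),
        )

        for hybrid in HYBRIDS:
            totals, total_libs = sub.hybrid_totals(hybrid)
            for parent, pcols in (("Cbr", cbr_cols), ("Cni", cni_cols)):
                counts = pd.concat([totals, sub.counts[pcols]], axis=1)
                libs = pd.concat([total_libs, t.library_sizes[pcols]])
                frames[f"{hybrid}_vs_{parent}"] = (
                    counts,
                    libs,
                    detest.Contrast(
                        tuple(totals.columns),
                        tuple(pcols),
                        f"{hybrid} vs {parent}",
                    ),
                )
            a_cols = t.columns_for(f"{hybrid}_cbr")
            b_cols = t.columns_for(f"{hybrid}_cni")
            counts = sub.counts[a_cols + b_cols]
            libs = t.library_sizes[a_cols + b_cols]
            frames[f"allele_{hybrid}"] = (
                counts,
                libs,
                detest.Contrast(
                    tuple(a_cols), tuple(b_cols),
                    f"{hybrid}_cbr vs {hybrid}_cni",
                ),
            )
        return frames

    def fit(self) -> "HybridAseResults":
        """Run the whole analysis and return the results object."""
        th = self.thresholds
        cpm_full = self.table.cpm()
        expressed = quantify.filter_expressed(
            cpm_full,
            min_cpm=th.filter_min_cpm,
            min_columns=th.filter_min_columns,
        )
        if len(expressed) == 0:
            raise ValueError("no pairs pass the expression filter")

        de = {
            name: detest.run_de(counts, libs, contrast, dispersion=self.dispersion)
            for name, (counts, libs, contrast) in self._contrast_frames(
                expressed
            ).items()
        }

        inh = pd.concat(
            [
                inheritance.call_table(
                    de[f"{h}_vs_Cbr"],
                    de[f"{h}_vs_Cni"],
                    h,
                    alpha=th.alpha_fdr,
                    lfc_cut=th.lfc_cut,
                )
                for h in HYBRIDS
            ]
        )
        reg = pd.concat(
            [
                regulatory.call_table(
                    de["parental"],
                    de[f"allele_{h}"],
                    h,
                    alpha=th.alpha_fdr,
                    delta=th.reg_delta,
                )
                for h in HYBRIDS
            ]
        )

        mean_cpm = pd.DataFrame(
            {
                g: cpm_full.loc[expressed, self.table.columns_for(g)].mean(axis=1)
                for g in ("BN_cbr", "BN_cni", "NB_cbr", "NB_cni")
            }
        )
        imp = imprinting.call_table(
            mean_cpm, cutoff=th.imprint_cutoff, min_total=th.imprint_min_cpm
        )

        return HybridAseResults(
            model=self,
            expressed=expressed,
            de=de,
            inheritance_calls=inh,
            regulatory_calls=reg,
            imprint_calls=imp,
        )


@dataclass
class HybridAseResults:
    """Fitted classifications plus their summary statistics.

    Attributes
    ----------
    expressed : pandas.Index
        Pair ids passing the expression filter (the analysis universe).
    de : dict
        ``run_de`` tables for the seven contrasts: ``parental``,
        ``{BN,NB}_vs_{Cbr,Cni}`` and ``allele_{BN,NB}``.
    inheritance_calls, regulatory_calls : pandas.DataFrame
        One row per pair per hybrid with supporting statistics and the
        assigned ``category``.
    imprint_calls : pandas.DataFrame
        Allelic fractions, imprint status and maternal/paternal leaning.
    """

    model: HybridAseModel
    expressed: pd.Index
    de: dict[str, pd.DataFrame]
    inheritance_calls: pd.DataFrame
    regulatory_calls: pd.DataFrame
    imprint_calls: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # -- per-hybrid views ------------------------------------------------

    def inheritance(self, hybrid: str) -> pd.Series:
        df = self.inheritance_calls
        return df.loc[df["hybrid"] == hybrid, "category"]

    def regulatory(self, hybrid: str) -> pd.Series:
        df = self.regulatory_calls
        return df.loc[df["hybrid"] == hybrid, "category"]

    # -- summaries -------------------------------------------------------

    def inheritance_proportions(self, hybrid: str) -> pd.DataFrame:
        return inheritance.category_proportions(self.inheritance(hybrid))

    def regulatory_proportions(self, hybrid: str) -> pd.DataFrame:
        return inheritance.category_proportions(
            self.regulatory(hybrid), categories=regulatory.CATEGORIES
        )

    def venn(self, which: str = "inheritance") -> dict:
        """Shared / BN-only / NB-only pair sets per category."""
        if which == "inheritance":
            return inheritance.compare_hybrids(
                self.inheritance("BN"), self.inheritance("NB")
            )
        if which == "regulatory":
            return inheritance.compare_hybrids(
                self.regulatory("BN"),
                self.regulatory("NB"),
                categories=regulatory.CATEGORIES,
            )
        raise ValueError(f"unknown venn kind {which!r}")

    def cross_tabulation(self, hybrid: str) -> pd.DataFrame:
        """Proportion of each inheritance category in each regulatory class."""
        return regulatory.cross_tabulate(
            self.inheritance(hybrid), self.regulatory(hybrid)
        )

    def allele_contrast_summary(self) -> dict[str, list[str]]:
        """Alleles differentially expressed within each hybrid, and shared.

        Per hybrid, pairs with raw p < ``alpha_raw`` and |log2fc| >
        ``lfc_cut`` in the within-hybrid allele contrast are split into
        Cbr-up (log2fc > 0) and Cni-up; ``both_cbr_up`` / ``both_cni_up``
        are the cross-hybrid intersections.
        """
        th = self.model.thresholds
        out: dict[str, list[str]] = {}
        per_hybrid = {}
        for h in HYBRIDS:
            de = self.de[f"allele_{h}"]
            sig = (de["pvalue"] < th.alpha_raw) & (
                de["log2fc"].abs() > th.lfc_cut
            )
            per_hybrid[h] = {
                "cbr_up": set(de.index[sig & (de["log2fc"] > 0)]),
                "cni_up": set(de.index[sig & (de["log2fc"] < 0)]),
            }
            out[f"{h}_cbr_up"] = sorted(per_hybrid[h]["cbr_up"])
            out[f"{h}_cni_up"] = sorted(per_hybrid[h]["cni_up"])
        out["both_cbr_up"] = sorted(
            per_hybrid["BN"]["cbr_up"] & per_hybrid["NB"]["cbr_up"]
        )
        out["both_cni_up"] = sorted(
            per_hybrid["BN"]["cni_up"] & per_hybrid["NB"]["cni_up"]
        )
        return out

    def chromosome_enrichment(
        self, which: str = "inheritance", hybrid: str = "BN"
    ) -> pd.DataFrame:
        if self.model.chromosomes is None:
            raise ValueError("model was built without chromosome labels")
        th = self.model.thresholds
        calls = (
            self.inheritance(hybrid)
            if which == "inheritance"
            else self.regulatory(hybrid)
        )
        return enrichment.chromosome_enrichment(
            calls,
            self.model.chromosomes,
            alpha=th.enrich_alpha,
            lor_cut=th.enrich_lor_cut,
        )

    def imprint_counts(self) -> dict[str, int]:
        status = self.imprint_calls["status"]
        leaning = self.imprint_calls["leaning"]
        return {
            "maternal_imprinted": int((status == "maternal").sum()),
            "paternal_imprinted": int((status == "paternal").sum()),
            "maternal_leaning": int((leaning == "maternal").sum()),
            "paternal_leaning": int((leaning == "paternal").sum()),
        }

    def summary(self) -> str:
        """Human-readable overview of the fitted classifications."""
        lines = [
            "Hybrid allele-specific expression analysis",
            "=" * 44,
            f"expressed ortholog pairs: {len(self.expressed)}",
            "",
        ]
        for h in HYBRIDS:
            props = self.inheritance_proportions(h)
            lines.append(f"[{h}] inheritance modes")
            for cat, row in props.iterrows():
                lines.append(
                    f"  {cat:<14} {int(row['count']):>6}"
                    f"  ({100 * row['fraction']:.1f}%)"
                )
            props = self.regulatory_proportions(h)
            lines.append(f"[{h}] regulatory classes")
            for cat, row in props.iterrows():
                lines.append(
                    f"  {cat:<14} {int(row['count']):>6}"
                    f"  ({100 * row['fraction']:.1f}%)"
                )
            lines.append("")
        imp = self.imprint_counts()
        lines.append(
            f"imprinted genes: {imp['maternal_imprinted']} maternal, "
            f"{imp['paternal_imprinted']} paternal"
        )
        lines.append(
            f"parental leaning: {imp['maternal_leaning']} maternal, "
            f"{imp['paternal_leaning']} paternal"
        )
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        """JSON-serialisable summary (counts, fractions, Venn cells)."""
        def venn_counts(v):
            return {
                cat: {part: len(ids) for part, ids in cells.items()}
                for cat, cells in v.items()
            }

        summary = {
            "n_expressed": int(len(self.expressed)),
            "thresholds": asdict(self.model.thresholds),
            "inheritance": {},
            "regulatory": {},
            "imprinting": self.imprint_counts(),
            "venn": {
                "inheritance": venn_counts(self.venn("inheritance")),
                "regulatory": venn_counts(self.venn("regulatory")),
            },
            "allele_contrast": {
                k: len(v) for k, v in self.allele_contrast_summary().items()
            },
        }
        for h in HYBRIDS:
            summary["inheritance"][h] = {
                cat: {
                    "count": int(row["count"]),
                    "fraction": round(float(row["fraction"]), 3),
                }
                for cat, row in self.inheritance_proportions(h).iterrows()
            }
            summary["regulatory"][h] = {
                cat: {
                    "count": int(row["count"]),
                    "fraction": round(float(row["fraction"]), 3),
                }
                for cat, row in self.regulatory_proportions(h).iterrows()
            }
        return summary

    def save(self, outdir) -> dict[str, Path]:
        """Write per-stage TSVs; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in self.de.items():
            p = outdir / f"de_{name}.tsv"
            table.to_csv(p, sep="\t", float_format="%.6g")
            paths[f"de_{name}"] = p
        for name, table in (
            ("inheritance_calls", self.inheritance_calls),
            ("regulatory_calls", self.regulatory_calls),
            ("imprint_calls", self.imprint_calls),
        ):
            p = outdir / f"{name}.tsv"
            table.to_csv(p, sep="\t", float_format="%.6g")
            paths[name] = p
        return paths
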