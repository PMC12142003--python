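"""Synthetic allele-resolved count experiments with known ground truth.

The generator emulates the study design the analysis expects: three Cni
replicates, two replicates each of Cbr and of the reciprocal hybrids BN and
NB, with each hybrid replicate split into two haplotype columns (13 count
columns in the default design).  Every ortholog pair carries a true
inheritance class, a true regulatory class and a true imprint status, and
counts are drawn from a negative binomial with ``variance = mu + phi*mu**2``.

Generative rules per class (log2-CPM scale; ``e`` = ``effect_size``):

==============  =======================================================
class           constraint
==============  =======================================================
no_change       parental divergence d = 0, hybrid total = parents
cbr_dominant    |d| >= e, hybrid total = Cbr level
cni_dominant    |d| >= e, hybrid total = Cni level
additive        |d| >= e, hybrid total = parental log2 midpoint
overdominant    hybrid total = max(parents) + e
underdominant   hybrid total = min(parents) - e
conserved       d = 0 and allele log2 ratio r = 0 (requires no_change)
cis             r = d, |d| >= e
trans           r = 0 with |d| >= e (allele ratio equalised)
==============  =======================================================

A gene's regulatory class must be compatible with its inheritance class:
``conserved`` forces d = 0 and is therefore only compatible with
``no_change``, while ``cis``/``trans`` require |d| >= e and are compatible
with every class except ``no_change``.  Incompatible mixes are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hybridase import quantify

INHERITANCE_CLASSES = (
    "no_change",
    "cbr_dominant",
    "cni_dominant",
    "additive",
    "overdominant",
    "underdominant",
)
REGULATORY_CLASSES = ("conserved", "cis", "trans")
CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")


def _default_class_mix() -> dict[str, float]:
    return {c: 1.0 / 6.0 for c in INHERITANCE_CLASSES}


def _default_reg_mix() -> dict[str, float]:
    # conserved must match the no_change share; cis dominates trans, as is
    # typical for closely related species
    return {"conserved": 1.0 / 6.0, "cis": 2.0 / 3.0, "trans": 1.0 / 6.0}


def _default_replicates() -> dict[str, int]:
    return {"Cni": 3, "Cbr": 2, "BN": 2, "NB": 2}


@dataclass
class ScenarioConfig:
    """Parameters of one simulated experiment.

    Attributes
    ----------
    n_orthologs : int
        Number of one-to-one ortholog pairs.
    class_mix, reg_mix : dict
        Proportions per inheritance / regulatory class; each must sum to 1.
    n_imprinted_maternal, n_imprinted_paternal : int
        Imprinted genes, carved from the no_change/conserved pool.
    imprint_fraction : float
        Expression share of the imprinted (favoured) allele.
    effect_size : float
        Minimum class effect in log2 units.
    dispersion : float
        NB dispersion phi >= 0 (variance = mu + phi*mu^2).
    mean_log2_expr_range : tuple
        Bounds of the baseline log2-CPM mean mu.
    lib_size_mean, lib_size_cv : float
        Mean and coefficient of variation of per-library read totals.
    replicates : dict
        Replicates per group; each hybrid replicate yields two haplotype
        columns.
    x_fraction : float
        Probability a gene sits on the X chromosome (autosomes uniform).
    """

    n_orthologs: int = 3000
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    reg_mix: dict[str, float] = field(default_factory=_default_reg_mix)
    n_imprinted_maternal: int = 0
    n_imprinted_paternal: int = 0
    imprint_fraction: float = 0.9
    effect_size: float = 2.0
    dispersion: float = 0.05
    mean_log2_expr_range: tuple[float, float] = (3.0, 10.0)
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.2
    replicates: dict[str, int] = field(default_factory=_default_replicates)
    x_fraction: float = 0.15
    n_gene_sets: int = 5
    gene_set_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_orthologs <= 0:
            raise ValueError("n_orthologs must be positive")
        for name, mix, allowed in (
            ("class_mix", self.class_mix, INHERITANCE_CLASSES),
            ("reg_mix", self.reg_mix, REGULATORY_CLASSES),
        ):
            unknown = set(mix) - set(allowed)
            if unknown:
                raise ValueError(f"{name}: unknown classes {sorted(unknown)}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name}: negative proportion")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_imprinted_maternal < 0 or self.n_imprinted_paternal < 0:
            raise ValueError("imprinted gene counts must be >= 0")
        if not 0.5 < self.imprint_fraction <= 1.0:
            raise ValueError("imprint_fraction must lie in (0.5, 1]")
        if any(v < 1 for v in self.replicates.values()):
            raise ValueError("every group needs at least one replicate")

        # joint feasibility: conserved pairs only with no_change, cis/trans
        # only with classes allowing |d| >= effect_size
        conserved = self.reg_mix.get("conserved", 0.0)
        no_change = self.class_mix.get("no_change", 0.0)
        if conserved - no_change > 1e-9:
            other = max(
                (c for c in self.class_mix if c != "no_change"),
                key=lambda c: self.class_mix[c],
                default="overdominant",
            )
            raise ValueError(
                "inconsistent mixes: regulatory 'conserved' (requires zero "
                f"parental divergence) cannot be paired with inheritance "
                f"'{other}' — conserved share {conserved:.3f} exceeds the "
                f"no_change share {no_change:.3f}"
            )
        if no_change - conserved > 1e-9:
            other = "cis" if self.reg_mix.get("cis", 0) >= self.reg_mix.get(
                "trans", 0
            ) else "trans"
            raise ValueError(
                f"inconsistent mixes: inheritance 'no_change' (zero "
                f"divergence) cannot be paired with regulatory '{other}' "
                f"(requires |divergence| >= effect_size) — no_change share "
                f"{no_change:.3f} exceeds the conserved share {conserved:.3f}"
            )


def _exact_counts(total: int, mix: dict[str, float], order) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` items across classes."""
    keys = [k for k in order if mix.get(k, 0.0) > 0]
    raw = np.array([mix[k] * total for k in keys])
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    by_frac = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[by_frac[i]] += 1
    return dict(zip(keys, counts))


def build_truth(config: ScenarioConfig) -> pd.DataFrame:
    """Draw per-ortholog generative parameters and true class labels.

    Deterministic given ``config.seed``.  Returns one row per ortholog with
    the baseline log2 mean ``mu``, the parental divergence
    ``d = log2(Cbr/Cni)``, the hybrid total log2 expression ``t_log2``
    (identical in both hybrids), the per-hybrid C. briggsae allele fractions
    ``f_cbr_bn`` / ``f_cbr_nb``, class labels and gene-set memberships.
    """
    config.validate()
    n = config.n_orthologs
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    r_class, r_param, r_chrom, r_sets, r_imprint, _ = rngs

    inh_counts = _exact_counts(n, config.class_mix, INHERITANCE_CLASSES)
    inh = np.array(
        [c for c, k in inh_counts.items() for _ in range(k)], dtype=object
    )
    r_class.shuffle(inh)

    # regulatory classes: conserved is pinned to no_change; cis/trans are
    # apportioned within the remaining genes
    reg = np.empty(n, dtype=object)
    no_change_idx = np.flatnonzero(inh == "no_change")
    reg[no_change_idx] = "conserved"
    other_idx = np.flatnonzero(inh != "no_change")
    ct_mix = {
        k: config.reg_mix.get(k, 0.0) for k in ("cis", "trans")
    }
    ct_total = sum(ct_mix.values())
    if other_idx.size:
        if ct_total <= 0:
            raise ValueError(
                "inconsistent mixes: non-no_change inheritance classes "
                "requested but reg_mix assigns no mass to 'cis'/'trans'"
            )
        ct_mix = {k: v / ct_total for k, v in ct_mix.items()}
        ct_counts = _exact_counts(other_idx.size, ct_mix, ("cis", "trans"))
        ct = np.array(
            [c for c, k in ct_counts.items() for _ in range(k)], dtype=object
        )
        r_class.shuffle(ct)
        reg[other_idx] = ct

    lo, hi = config.mean_log2_expr_range
    mu = r_param.uniform(lo, hi, size=n)

    e = config.effect_size
    needs_d = ~np.isin(inh, ["no_change"]) & (
        np.isin(inh, ["cbr_dominant", "cni_dominant", "additive"])
        | np.isin(reg, ["cis", "trans"])
    )
    magnitude = r_param.uniform(e, 2 * e, size=n)
    sign = r_param.choice([-1.0, 1.0], size=n)
    d = np.where(needs_d, sign * magnitude, 0.0)

    cbr = mu + d / 2.0
    cni = mu - d / 2.0
    t_log2 = np.select(
        [
            inh == "no_change",
            inh == "cbr_dominant",
            inh == "cni_dominant",
            inh == "additive",
            inh == "overdominant",
            inh == "underdominant",
        ],
        [mu, cbr, cni, mu, np.maximum(cbr, cni) + e, np.minimum(cbr, cni) - e],
    )

    r = np.where(reg == "cis", d, 0.0)
    f_cbr = 2.0**r / (1.0 + 2.0**r)
    f_cbr_bn = f_cbr.copy()
    f_cbr_nb = f_cbr.copy()

    # imprinting: carve from the no_change/conserved pool so the allelic
    # skew is a pure parent-of-origin effect
    imprint = np.full(n, "none", dtype=object)
    n_imp = config.n_imprinted_maternal + config.n_imprinted_paternal
    if n_imp:
        if n_imp > no_change_idx.size:
            raise ValueError(
                f"{n_imp} imprinted genes requested but only "
                f"{no_change_idx.size} no_change genes available"
            )
        chosen = r_imprint.choice(no_change_idx, size=n_imp, replace=False)
        maternal = chosen[: config.n_imprinted_maternal]
        paternal = chosen[config.n_imprinted_maternal:]
        f = config.imprint_fraction
        # in BN the mother is C. nigoni, in NB the mother is C. briggsae
        imprint[maternal] = "maternal"
        f_cbr_bn[maternal] = 1.0 - f
        f_cbr_nb[maternal] = f
        imprint[paternal] = "paternal"
        f_cbr_bn[paternal] = f
        f_cbr_nb[paternal] = 1.0 - f

    chrom = np.where(
        r_chrom.random(n) < config.x_fraction,
        "X",
        r_chrom.choice(CHROMOSOMES[:5], size=n),
    )

    set_names = [f"set_{i + 1}" for i in range(config.n_gene_sets)]
    membership = r_sets.random((n, config.n_gene_sets)) < config.gene_set_fraction
    gene_sets = [
        ";".join(s for s, m in zip(set_names, row) if m) for row in membership
    ]

    width = len(str(n))
    return pd.DataFrame(
        {
            "pair_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "cbr_gene": [f"CBR_{i + 1:0{width}d}" for i in range(n)],
            "cni_gene": [f"CNI_{i + 1:0{width}d}" for i in range(n)],
            "chromosome": chrom,
            "mu": mu,
            "d": d,
            "t_log2": t_log2,
            "r_bn": np.log2(f_cbr_bn / (1 - f_cbr_bn)),
            "r_nb": np.log2(f_cbr_nb / (1 - f_cbr_nb)),
            "offset": t_log2 - mu,
            "f_cbr_bn": f_cbr_bn,
            "f_cbr_nb": f_cbr_nb,
            "inheritance_class": inh,
            "regulatory_class": reg,
            "imprint_status": imprint,
            "gene_sets": gene_sets,
        }
    ).set_index("pair_id")


@dataclass
class SimulatedExperiment:
    """Gene-level counts plus the metadata needed to analyse them."""

    gene_counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    ortholog_map: pd.DataFrame
    library_sizes: pd.Series
    truth: pd.DataFrame
    config: ScenarioConfig

    def to_allele_table(self) -> quantify.AlleleCountTable:
        """Assemble the pair-level table through the standard reader path."""
        return quantify.assemble_groups(
            self.gene_counts, self.sample_sheet, self.ortholog_map
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float):
    mean = np.maximum(mean, 1e-12)
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    truth: pd.DataFrame, config: ScenarioConfig
) -> SimulatedExperiment:
    """Draw NB counts for every column of the design.

    Parental columns draw NB(expected CPM x lib/1e6, phi) directly.  Each
    hybrid replicate draws its per-gene *total* count the same way and then
    splits it binomially between the two haplotype columns according to the
    gene's C. briggsae allele fraction, so allele counts are conserved by
    construction.  Deterministic given ``config.seed``.
    """
    config.validate()
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n = len(truth)
    root = np.random.SeedSequence((config.seed, 1))
    r_lib, r_counts, r_split = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    cbr_cpm = 2.0 ** (truth["mu"] + truth["d"] / 2.0)
    cni_cpm = 2.0 ** (truth["mu"] - truth["d"] / 2.0)
    total_cpm = 2.0 ** truth["t_log2"]

    def draw_lib() -> float:
        if config.lib_size_cv <= 0:
            return float(config.lib_size_mean)
        sigma = np.sqrt(np.log1p(config.lib_size_cv**2))
        return float(
            config.lib_size_mean
            * np.exp(r_lib.normal(-0.5 * sigma**2, sigma))
        )

    phi = config.dispersion
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    lib_sizes: dict[str, float] = {}
    sheet_rows = []

    zeros = np.zeros(n, dtype=np.int64)
    for species, cpm_vec in (("Cbr", cbr_cpm), ("Cni", cni_cpm)):
        for rep in range(1, config.replicates[species] + 1):
            lib = draw_lib()
            col = f"{species}_{rep}"
            own = _nb_draw(r_counts, cpm_vec.to_numpy() * lib / 1e6, phi)
            columns[col] = own
            groups[col] = species
            lib_sizes[col] = lib
            sheet_rows.append((col, species, rep))

    frac = {"BN": truth["f_cbr_bn"].to_numpy(), "NB": truth["f_cbr_nb"].to_numpy()}
    for hybrid in ("BN", "NB"):
        for rep in range(1, config.replicates[hybrid] + 1):
            lib = draw_lib()
            total = _nb_draw(r_counts, total_cpm.to_numpy() * lib / 1e6, phi)
            cbr_part = r_split.binomial(total, frac[hybrid])
            for hap, part in (("cbr", cbr_part), ("cni", total - cbr_part)):
                col = f"{hybrid}_{hap}_{rep}"
                columns[col] = part
                groups[col] = f"{hybrid}_{hap}"
                lib_sizes[col] = lib
                sheet_rows.append((col, f"{hybrid}_{hap}", rep))

    # gene-level table: each column's counts live on the rows of the
    # haplotype it measures; the other species' rows are zero
    gene_index = pd.Index(
        list(truth["cbr_gene"]) + list(truth["cni_gene"]), name="feature_id"
    )
    gene_cols = {}
    for col, vals in columns.items():
        species = quantify.GROUP_SPECIES[groups[col]]
        top = vals if species == "cbr" else zeros
        bottom = vals if species == "cni" else zeros
        gene_cols[col] = np.concatenate([top, bottom])
    gene_counts = pd.DataFrame(gene_cols, index=gene_index)

    sheet = pd.DataFrame(sheet_rows, columns=["column_id", "group", "replicate"])
    omap = truth.reset_index()[["pair_id", "cbr_gene", "cni_gene", "chromosome"]]
    return SimulatedExperiment(
        gene_counts=gene_counts,
        sample_sheet=sheet,
        ortholog_map=omap,
        library_sizes=pd.Series(lib_sizes),
        truth=truth,
        config=config,
    )


def write_fixtures(experiment: SimulatedExperiment, directory) -> dict[str, Path]:
    """Write the experiment as the plain-text bundle the pipeline reads.

    Emits ``counts.tsv``, ``sample_sheet.tsv``, ``ortholog_map.tsv``,
    ``chromosomes.tsv``, ``gene_sets.gmt``, ``truth.tsv`` and
    ``library_sizes.tsv``; the counts/sheet/map files round-trip losslessly
    through :func:`hybridase.quantify.assemble_groups`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, writer) -> None:
        path = directory / name
        try:
            writer(path)
        except OSError as err:
            raise OSError(f"cannot write fixture {path}: {err}") from err
        paths[name] = path

    _write("counts.tsv", lambda p: experiment.gene_counts.to_csv(p, sep="\t"))
    _write(
        "sample_sheet.tsv",
        lambda p: experiment.sample_sheet.to_csv(p, sep="\t", index=False),
    )
    _write(
        "ortholog_map.tsv",
        lambda p: experiment.ortholog_map.to_csv(p, sep="\t", index=False),
    )
    _write(
        "chromosomes.tsv",
        lambda p: experiment.truth.reset_index()[["pair_id", "chromosome"]].to_csv(
            p, sep="\t", index=False
        ),
    )
    _write("truth.tsv", lambda p: experiment.truth.to_csv(p, sep="\t"))
    _write(
        "library_sizes.tsv",
        lambda p: experiment.library_sizes.rename("library_size")
        .rename_axis("column_id")
        .to_csv(p, sep="\t"),
    )

    sets: dict[str, list[str]] = {}
    for pair_id, names in experiment.truth["gene_sets"].items():
        if not names:
            continue
        for s in str(names).split(";"):
            sets.setdefault(s, []).append(pair_id)

    def _write_gmt(path: Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(sets):
                members = "\t".join(sets[name])
                fh.write(f"{name}\tsynthetic gene set\t{members}\n")

    _write("gene_sets.gmt", _write_gmt)
    _write(
        "scenario.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(experiment.config).items()
                },
                indent=2,
                sort_keys=True,
            )
        ),
    )
    return paths
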