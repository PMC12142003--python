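"""Haplotype-resolved count assembly, CPM normalisation and expression filtering.

The experimental design has six expression groups: the two parental species
(``Cbr``, ``Cni``) and, for each reciprocal hybrid (``BN`` = C. briggsae
father x C. nigoni mother, ``NB`` = the reverse cross), one column per
haplotype (``BN_cbr``, ``BN_cni``, ``NB_cbr``, ``NB_cni``).  With 3 Cni
replicates and 2 replicates for every other group the default design yields
13 count columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("Cni", "Cbr", "BN_cbr", "BN_cni", "NB_cbr", "NB_cni")

#: which species' haplotype each group measures
GROUP_SPECIES = {
    "Cni": "cni",
    "Cbr": "cbr",
    "BN_cbr": "cbr",
    "BN_cni": "cni",
    "NB_cbr": "cbr",
    "NB_cni": "cni",
}


@dataclass
class AlleleCountTable:
    """Integer counts per ortholog pair with a column-to-group mapping.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix, one row per ortholog pair, one column per
        sample/haplotype.
    groups : dict
        Mapping ``column_id -> group`` with group one of :data:`GROUPS`.
    library_sizes : pandas.Series
        Reads per column used as the CPM denominator.  Defaults to the
        column totals of ``counts``.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        unknown = set(self.groups.values()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown expression groups: {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"columns missing from group mapping: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    @property
    def pair_ids(self) -> pd.Index:
        return self.counts.index

    def columns_for(self, group: str) -> list[str]:
        """Column ids belonging to one expression group, in table order."""
        return [c for c in self.counts.columns if self.groups[c] == group]

    def hybrid_totals(self, hybrid: str) -> tuple[pd.DataFrame, pd.Series]:
        """Total (both-haplotype) counts per hybrid replicate.

        Haplotype columns are paired by replicate in column order; each
        replicate's two columns are summed, and the replicate library size is
        the sum of the two haplotype library sizes.
        """
        cbr_cols = self.columns_for(f"{hybrid}_cbr")
        cni_cols = self.columns_for(f"{hybrid}_cni")
        if len(cbr_cols) != len(cni_cols):
            raise ValueError(f"unpaired haplotype columns for hybrid {hybrid}")
        total = {}
        libs = {}
        for i, (a, b) in enumerate(zip(cbr_cols, cni_cols), start=1):
            name = f"{hybrid}_total_{i}"
            total[name] = self.counts[a] + self.counts[b]
            libs[name] = float(self.library_sizes[a] + self.library_sizes[b])
        return pd.DataFrame(total, index=self.counts.index), pd.Series(libs)

    def cpm(self) -> pd.DataFrame:
        return cpm(self.counts, self.library_sizes)

    def subset(self, pair_ids) -> "AlleleCountTable":
        return AlleleCountTable(
            self.counts.loc[pair_ids], dict(self.groups), self.library_sizes
        )


@dataclass
class AmbiguityStats:
    """Per-dataset read-assignment summary from dual-genome alignment."""

    n_reads: int
    n_ambiguous: int
    n_assigned_cbr: int
    n_assigned_cni: int

    @property
    def ambiguous_fraction(self) -> float:
        return self.n_ambiguous / self.n_reads if self.n_reads else 0.0


def cpm(counts, library_sizes) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / library_size`` per column.

    When ``library_sizes`` are the column totals of the full (unfiltered)
    table, every column of the resulting matrix sums to exactly 1e6.
    """
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    out = np.asarray(counts, dtype=float) * 1e6 / libs[np.newaxis, :]
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_expressed(
    cpm_matrix, min_cpm: float = 2.0, min_columns: int = 4, strict: bool = True
):
    """Feature ids passing the expression filter.

    A feature is kept iff its CPM exceeds ``min_cpm`` (strictly, by default)
    in at least ``min_columns`` columns.  The default (CPM > 2 in >= 4 of the
    13 haplotype-level columns) is applied before every differential test.
    ``strict=False`` switches to ``>=``, the convention used for the
    transposable-element track.
    """
    values = np.asarray(cpm_matrix, dtype=float)
    if values.shape[1] < min_columns:
        raise ValueError(
            f"matrix has {values.shape[1]} columns < min_columns={min_columns}"
        )
    passing = values > min_cpm if strict else values >= min_cpm
    keep = passing.sum(axis=1) >= min_columns
    if isinstance(cpm_matrix, pd.DataFrame):
        return cpm_matrix.index[keep]
    return np.nonzero(keep)[0]


def mapping_ambiguity(read_records: pd.DataFrame) -> AmbiguityStats:
    """Classify reads aligned against both parental genomes.

    A read with mapping-quality > 0 alignments to both species is ambiguous;
    with MQ > 0 alignments to a single species it is assigned to that
    species.  Reads whose alignments are all MQ = 0 (pure multimappers) are
    excluded from the denominator.

    Parameters
    ----------
    read_records : pandas.DataFrame
        Columns ``read_id``, ``species`` in {"cbr", "cni"}, ``mapq``.
    """
    unknown = set(read_records["species"].unique()) - {"cbr", "cni"}
    if unknown:
        raise ValueError(f"unknown species labels: {sorted(unknown)}")
    informative = read_records[read_records["mapq"] > 0]
    per_read = informative.groupby("read_id")["species"].agg(frozenset)
    n_amb = int((per_read == frozenset({"cbr", "cni"})).sum())
    n_cbr = int((per_read == frozenset({"cbr"})).sum())
    n_cni = int((per_read == frozenset({"cni"})).sum())
    return AmbiguityStats(
        n_reads=len(per_read),
        n_ambiguous=n_amb,
        n_assigned_cbr=n_cbr,
        n_assigned_cni=n_cni,
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns NaN with a warning for a constant input, where the statistic is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman undefined for a constant vector", RuntimeWarning)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def assemble_groups(
    gene_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    ortholog_map: pd.DataFrame,
) -> AlleleCountTable:
    """Build the pair-level allele count table from gene-level counts.

    Each column of ``gene_counts`` is mapped to one of the six expression
    groups through the sample sheet.  For every ortholog pair, a column's
    count is taken from the gene of the haplotype that column measures
    (e.g. parental Cbr columns and hybrid ``*_cbr`` columns read the
    *C. briggsae* gene's row); counts that sit on the other species'
    haplotype rows are thereby dropped, which for parental samples removes
    cross-species mismatches.

    Parameters
    ----------
    gene_counts : pandas.DataFrame
        Gene-level integer counts, rows indexed by gene id (both species).
    sample_sheet : pandas.DataFrame
        Columns ``column_id``, ``group``, ``replicate``.
    ortholog_map : pandas.DataFrame
        Columns ``pair_id``, ``cbr_gene``, ``cni_gene`` (and optionally
        ``chromosome``).

    Returns
    -------
    AlleleCountTable
        One row per ortholog pair, one column per sample/haplotype; library
        sizes are the column totals of ``gene_counts`` (the full pre-filter
        normalisation background).
    """
    if sample_sheet.empty:
        raise ValueError("sample sheet is empty")
    sheet = sample_sheet.set_index("column_id")["group"]
    missing = set(gene_counts.columns) - set(sheet.index)
    if missing:
        raise ValueError(f"counts columns missing from sample sheet: {sorted(missing)}")
    if ortholog_map["pair_id"].duplicated().any():
        dups = ortholog_map.loc[ortholog_map["pair_id"].duplicated(), "pair_id"]
        raise ValueError(f"duplicate pair ids in ortholog map: {list(dups[:5])}")

    pairs = ortholog_map.set_index("pair_id")
    gene_rows = {
        "cbr": gene_counts.reindex(pairs["cbr_gene"]).fillna(0).to_numpy(),
        "cni": gene_counts.reindex(pairs["cni_gene"]).fillna(0).to_numpy(),
    }
    col_index = {c: i for i, c in enumerate(gene_counts.columns)}
    assembled = {}
    groups = {}
    for col in gene_counts.columns:
        group = sheet[col]
        species = GROUP_SPECIES[group]
        assembled[col] = gene_rows[species][:, col_index[col]]
        groups[col] = group
    table = pd.DataFrame(assembled, index=pairs.index).astype(int)
    lib = gene_counts.sum(axis=0).astype(float)
    return AlleleCountTable(table, groups, lib)
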