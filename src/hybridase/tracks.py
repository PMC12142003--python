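"""Mitochondria-restricted and transposable-element expression tracks.

Two side analyses reuse the DE machinery with special normalisation
backgrounds: nucleus-encoded mitochondria-related genes are normalised
against the summed counts of the mitochondria-related gene list only, and
TE families are normalised against the combined TE counts per column.
One-to-n homolog groups (e.g. genes sharing a human mitochondrial term)
have their expression summed before analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from hybridase import detest, quantify


def mito_library_sizes(counts: pd.DataFrame, mito_genes) -> pd.Series:
    """Per-column library sizes restricted to the mitochondria-related set.

    The returned sums are the CPM denominator for every mito-track analysis,
    so the mito gene set itself totals 1e6 CPM per column.
    """
    present = counts.index.intersection(pd.Index(mito_genes))
    if present.empty:
        raise ValueError("no mitochondria-related genes found in the counts")
    return counts.loc[present].sum(axis=0).astype(float)


def mito_term_expression(
    counts: pd.DataFrame, term_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Sum member-gene rows per reference term (term x column matrix)."""
    rows = {}
    for term, members in term_groups.items():
        present = [m for m in members if m in counts.index]
        absent = set(members) - set(present)
        if absent:
            warnings.warn(
                f"term {term}: skipping absent member(s) {sorted(absent)[:3]}",
                RuntimeWarning,
            )
        if not present:
            continue
        rows[term] = counts.loc[present].sum(axis=0)
    return pd.DataFrame(rows).T.rename_axis("term")


def te_filter(
    te_cpm: pd.DataFrame, min_cpm: float = 1.0, min_columns: int = 2
) -> pd.Index:
    """TE families expressed at CPM >= ``min_cpm`` in >= ``min_columns``.

    Same implementation as the mainstream expression filter, with the
    inclusive threshold the TE track uses.
    """
    return quantify.filter_expressed(
        te_cpm, min_cpm=min_cpm, min_columns=min_columns, strict=False
    )


def te_differential(
    te_counts: pd.DataFrame,
    cols_bn: list[str],
    cols_nb: list[str],
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """BN-vs-NB differential expression of TE families with raw-p flags.

    ``log2fc`` is oriented log2(BN/NB); families are flagged ``up_in_bn`` or
    ``up_in_nb`` by raw p < ``alpha`` and |log2fc| > ``lfc_cut`` (raw p, not
    FDR, is the significance field for this contrast).  Library sizes
    default to the combined TE counts per column — the single normalisation
    background the track uses.
    """
    if library_sizes is None:
        library_sizes = te_counts.sum(axis=0).astype(float)
    contrast = detest.Contrast(tuple(cols_bn), tuple(cols_nb), "TE: BN vs NB")
    de = detest.run_de(te_counts, library_sizes, contrast)
    sig = (de["pvalue"] < alpha) & (de["log2fc"].abs() > lfc_cut)
    de["flag"] = np.select(
        [sig & (de["log2fc"] > 0), sig & (de["log2fc"] < 0)],
        np.array(["up_in_bn", "up_in_nb"], dtype=object),
        default="ns",
    )
    return de
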