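"""Exact association and over-representation statistics.

Three flavours are used downstream: Fisher's exact test on 2x2 tables (via
the probability-mass two-sided rule), chromosome-by-category enrichment of
the classifier output with the |log2 odds ratio| > 0.4 and p < 0.01
significance convention, and hypergeometric over-representation of query
genes in GMT gene sets with BH-adjusted p-values and normalised gene counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from hybridase.detest import bh_fdr

DEFAULT_CHROM_ALPHA = 0.01
DEFAULT_LOR_CUT = 0.4


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = fields[2:]
    return sets


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on the table [[a, b], [c, d]].

    Two-sided p-values follow the probability-mass rule (sum of
    hypergeometric outcomes no more probable than the observed table).  The
    odds ratio is ``(a*d)/(b*c)``, with 0.5 added to every cell only when
    some cell is zero so the log2 odds ratio stays finite.

    Returns
    -------
    (odds_ratio, p)
        ``odds_ratio`` is NaN (with a warning) for an all-zero table.
    """
    cells = np.array([a, b, c, d])
    if (cells < 0).any():
        raise ValueError("table cells must be non-negative")
    if cells.sum() == 0:
        warnings.warn("all-zero 2x2 table: odds ratio undefined", RuntimeWarning)
        return float("nan"), 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if (cells == 0).any():
        a, b, c, d = cells + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def chromosome_enrichment(
    calls: pd.Series,
    chromosomes: pd.Series,
    alpha: float = DEFAULT_CHROM_ALPHA,
    lor_cut: float = DEFAULT_LOR_CUT,
    categories=None,
) -> pd.DataFrame:
    """Per chromosome x category 2x2 enrichment over the expressed universe.

    For every chromosome and category the table is (in-chromosome and
    in-category, in-chromosome not, out-of-chromosome in-category,
    out-of-chromosome not); a cell is flagged significant iff ``p < alpha``
    and ``|log2 odds ratio| > lor_cut``.

    Parameters
    ----------
    calls : pandas.Series
        pair id -> category over the expressed pairs (the background).
    chromosomes : pandas.Series
        pair id -> chromosome label; every pair in ``calls`` must be mapped.
    """
    missing = calls.index.difference(chromosomes.index)
    if len(missing):
        raise ValueError(
            f"pairs without a chromosome label: {list(missing[:5])}"
        )
    chrom = chromosomes[calls.index]
    chrom_labels = sorted(chrom.unique())
    if len(chrom_labels) < 2:
        warnings.warn(
            "single chromosome: all enrichment tables degenerate",
            RuntimeWarning,
        )
    if categories is None:
        categories = sorted(calls.unique())
    n_total = len(calls)
    rows = []
    for ch in chrom_labels:
        on = chrom == ch
        k_chrom = int(on.sum())
        for cat in categories:
            in_cat = calls == cat
            k = int((on & in_cat).sum())
            n_cat = int(in_cat.sum())
            a, b = k, k_chrom - k
            c, d = n_cat - k, n_total - k_chrom - (n_cat - k)
            degenerate = min(a + b, c + d) == 0 or min(a + c, b + d) == 0
            odds, p = fisher_2x2(a, b, c, d)
            lor = np.log2(odds) if np.isfinite(odds) and odds > 0 else np.nan
            rows.append(
                {
                    "unit": ch,
                    "category": cat,
                    "k": k,
                    "K": k_chrom,
                    "n": n_cat,
                    "N": n_total,
                    "odds_ratio": odds,
                    "log2_odds_ratio": lor,
                    "p": p,
                    "normalized_count": k / k_chrom if k_chrom else np.nan,
                    "significant": bool(
                        not degenerate
                        and p < alpha
                        and np.isfinite(lor)
                        and abs(lor) > lor_cut
                    ),
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def overrepresentation(
    query_genes,
    gene_sets: dict[str, list[str]],
    background,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in gene sets.

    Per set, the upper-tail p is ``P(X >= k)`` for ``k`` query hits out of
    a set of size ``K`` (after intersecting with the background of size
    ``N``) with a query of size ``n``; BH adjustment runs across sets.  The
    normalised gene count is ``k / K``, and a set is reported iff its FDR is
    below ``fdr_cutoff``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes) & background
    stray = set(query_genes) - background
    if stray:
        raise ValueError(
            f"query genes outside the background: {sorted(stray)[:5]}"
        )
    n = len(query)
    N = len(background)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "unit": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "normalized_count": k / K if K else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["reported"] = out["fdr"] < fdr_cutoff
    return out
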