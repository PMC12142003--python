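"""Cis/trans regulatory classification from parental and allelic contrasts.

Following the classic framework of Wittkopp and colleagues, each ortholog
pair is classified per hybrid by comparing the parental expression ratio
(P: Cbr vs Cni) with the allelic ratio inside the hybrid (H: the Cbr vs Cni
haplotype):

* ``conserved`` — no significant difference in either contrast;
* ``cis`` — divergence whose allelic ratio tracks the parental ratio (the
  difference of the two log2 ratios is small);
* ``trans`` — the remaining divergent genes, whose allelic ratio has been
  pulled away from the parental ratio by the hybrid cellular environment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CATEGORIES = ("conserved", "cis", "trans")

#: maximum |ratio_P - ratio_H| (log2) still called cis
DEFAULT_DELTA = 1.8


def log_ratio(expr_cbr, expr_cni, prior: float = 0.5):
    """log2((expr_cbr + prior) / (expr_cni + prior)) on mean CPMs."""
    a = np.asarray(expr_cbr, dtype=float)
    b = np.asarray(expr_cni, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(a + prior) - np.log2(b + prior)


def classify_regulatory(
    fdr_P,
    fdr_H,
    ratio_P,
    ratio_H,
    alpha: float = 0.05,
    delta: float = DEFAULT_DELTA,
):
    """Assign conserved / cis / trans per pair.

    ``conserved`` if neither the parental contrast (``fdr_P``) nor the
    within-hybrid allele contrast (``fdr_H``) is significant; otherwise
    ``cis`` if ``|ratio_P - ratio_H| < delta`` (log2 units), else ``trans``.
    """
    scalar = np.isscalar(fdr_P)
    fdr_P, fdr_H, ratio_P, ratio_H = (
        np.atleast_1d(np.asarray(v, dtype=float))
        for v in (fdr_P, fdr_H, ratio_P, ratio_H)
    )
    for name, v in (("fdr_P", fdr_P), ("fdr_H", fdr_H), ("ratio_P", ratio_P),
                    ("ratio_H", ratio_H)):
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in {name}")
    conserved = (fdr_P > alpha) & (fdr_H > alpha)
    cis = np.abs(ratio_P - ratio_H) < delta
    out = np.select(
        [conserved, cis],
        np.array(["conserved", "cis"], dtype=object),
        default="trans",
    )
    return out[0] if scalar else out


def call_table(
    de_parental: pd.DataFrame,
    de_allele: pd.DataFrame,
    hybrid: str,
    alpha: float = 0.05,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Per-pair regulatory calls for one hybrid.

    ``de_parental`` is the Cbr-vs-Cni contrast, ``de_allele`` the
    within-hybrid ``{hybrid}_cbr`` vs ``{hybrid}_cni`` contrast; both are
    ``run_de`` outputs whose ``log2fc`` is already the Cbr/Cni log2 ratio
    (computed with the pseudo-count prior).  Pairs with missing statistics
    are excluded with a warning.
    """
    if not de_parental.index.equals(de_allele.index):
        raise ValueError("DE tables are on different pair universes")
    stats = pd.DataFrame(
        {
            "ratio_P": de_parental["log2fc"],
            "ratio_H": de_allele["log2fc"],
            "fdr_P": de_parental["fdr"],
            "fdr_H": de_allele["fdr"],
        }
    )
    bad = ~np.isfinite(stats.to_numpy()).all(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} pair(s) with missing statistics",
            RuntimeWarning,
        )
        stats = stats[~bad]
    stats.insert(0, "hybrid", hybrid)
    stats["category"] = classify_regulatory(
        stats["fdr_P"], stats["fdr_H"], stats["ratio_P"], stats["ratio_H"],
        alpha=alpha, delta=delta,
    )
    stats["ratio_diff"] = np.abs(stats["ratio_P"] - stats["ratio_H"])
    return stats


def cross_tabulate(
    inh_calls: pd.Series,
    reg_calls: pd.Series,
    inh_categories=None,
    reg_categories=CATEGORIES,
) -> pd.DataFrame:
    """Proportion of each inheritance category in each regulatory class.

    Cell (i, r) is the number of pairs with inheritance ``i`` and regulatory
    class ``r`` divided by the number of pairs with inheritance ``i``; rows
    sum to 1.  An empty inheritance category yields an all-zero row with a
    warning.
    """
    from hybridase.inheritance import CATEGORIES as INH_CATEGORIES

    if inh_categories is None:
        inh_categories = INH_CATEGORIES
    common = inh_calls.index.intersection(reg_calls.index)
    if len(common) != len(inh_calls) or len(common) != len(reg_calls):
        raise ValueError("call tables are on different pair universes")
    table = pd.crosstab(inh_calls[common], reg_calls[common])
    table = table.reindex(
        index=inh_categories, columns=reg_categories, fill_value=0
    )
    totals = table.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"empty inheritance categories: {list(table.index[empty])}",
            RuntimeWarning,
        )
    props = table.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    props.index.name = "inheritance"
    props.columns.name = "regulatory"
    return props
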