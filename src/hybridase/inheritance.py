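"""Inheritance-mode classification of hybrid expression.

Each expressed ortholog pair is compared, per hybrid, against both parental
species and assigned exactly one of six categories: ``no_change``,
``cbr_dominant`` / ``cni_dominant`` (expression matches one parent),
``additive`` (intermediate), ``overdominant`` (above both parents) or
``underdominant`` (below both) — the transgressive categories being the
misexpression classes most relevant to hybrid dysfunction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CATEGORIES = (
    "no_change",
    "cbr_dominant",
    "cni_dominant",
    "additive",
    "overdominant",
    "underdominant",
)
TRANSGRESSIVE = ("overdominant", "underdominant")


def classify_inheritance(
    fdr_b,
    lfc_b,
    fdr_n,
    lfc_n,
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
):
    """Assign inheritance categories from the two hybrid-vs-parent tests.

    Inputs are vectors (or scalars): the BH-adjusted p-value and
    log2(hybrid/parent) fold change of the hybrid-vs-Cbr comparison
    (``fdr_b``, ``lfc_b``) and of the hybrid-vs-Cni comparison (``fdr_n``,
    ``lfc_n``).  Rules apply sequentially:

    1. ``no_change`` — not significant and |lfc| below the cutoff against
       *both* parents;
    2. dominant — the full "matches parent" clause (fdr > alpha and
       |lfc| < lfc_cut) holds for exactly one parent: matching Cbr gives
       ``cbr_dominant``, matching Cni ``cni_dominant``;
    3. ``underdominant`` — significant against both parents with both fold
       changes negative;
    4. ``overdominant`` — significant against both with both positive;
    5. otherwise ``additive``.

    Returns a numpy object array of category labels (or a single label for
    scalar input).  Missing values raise; exclude such pairs upstream.
    """
    scalar = np.isscalar(fdr_b)
    fdr_b, lfc_b, fdr_n, lfc_n = (
        np.atleast_1d(np.asarray(v, dtype=float))
        for v in (fdr_b, lfc_b, fdr_n, lfc_n)
    )
    for name, v in (("fdr_b", fdr_b), ("lfc_b", lfc_b), ("fdr_n", fdr_n),
                    ("lfc_n", lfc_n)):
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in {name}")

    match_b = (fdr_b > alpha) & (np.abs(lfc_b) < lfc_cut)
    match_n = (fdr_n > alpha) & (np.abs(lfc_n) < lfc_cut)
    sig_both = (fdr_b < alpha) & (fdr_n < alpha)

    out = np.select(
        [
            match_b & match_n,
            match_b & ~match_n,
            match_n & ~match_b,
            sig_both & (lfc_b < 0) & (lfc_n < 0),
            sig_both & (lfc_b > 0) & (lfc_n > 0),
        ],
        np.array(
            ["no_change", "cbr_dominant", "cni_dominant", "underdominant",
             "overdominant"],
            dtype=object,
        ),
        default="additive",
    )
    return out[0] if scalar else out


def call_table(
    de_vs_cbr: pd.DataFrame,
    de_vs_cni: pd.DataFrame,
    hybrid: str,
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-pair inheritance calls for one hybrid from two DE tables.

    ``de_vs_cbr`` / ``de_vs_cni`` are ``run_de`` outputs for the
    hybrid-total-vs-parent contrasts (log2fc oriented hybrid/parent) on the
    same pair universe.  Pairs with missing statistics are excluded with a
    warning rather than silently classified.
    """
    if not de_vs_cbr.index.equals(de_vs_cni.index):
        raise ValueError("DE tables are on different pair universes")
    stats = pd.DataFrame(
        {
            "fdr_vs_cbr": de_vs_cbr["fdr"],
            "lfc_vs_cbr": de_vs_cbr["log2fc"],
            "fdr_vs_cni": de_vs_cni["fdr"],
            "lfc_vs_cni": de_vs_cni["log2fc"],
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
    stats["category"] = classify_inheritance(
        stats["fdr_vs_cbr"],
        stats["lfc_vs_cbr"],
        stats["fdr_vs_cni"],
        stats["lfc_vs_cni"],
        alpha=alpha,
        lfc_cut=lfc_cut,
    )
    return stats


def compare_hybrids(
    calls_bn: pd.Series, calls_nb: pd.Series, categories=CATEGORIES
) -> dict[str, dict[str, list[str]]]:
    """Shared / BN-only / NB-only pair sets per category.

    Both inputs map pair id -> category over the same universe; per
    category the three sets are disjoint and their union is every pair
    holding the category in at least one hybrid.
    """
    if not calls_bn.index.sort_values().equals(calls_nb.index.sort_values()):
        raise ValueError("call tables are on different pair universes")
    out = {}
    for cat in categories:
        in_bn = set(calls_bn.index[calls_bn == cat])
        in_nb = set(calls_nb.index[calls_nb == cat])
        out[cat] = {
            "shared": sorted(in_bn & in_nb),
            "bn_only": sorted(in_bn - in_nb),
            "nb_only": sorted(in_nb - in_bn),
        }
    return out


def category_proportions(calls: pd.Series, categories=CATEGORIES) -> pd.DataFrame:
    """Count and fraction of pairs per category; fractions sum to 1."""
    if calls.empty:
        raise ValueError("empty call table")
    counts = calls.value_counts().reindex(categories, fill_value=0)
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    ).rename_axis("category")
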