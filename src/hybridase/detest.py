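"""Two-group negative-binomial exact differential expression.

This is the statistical engine behind every classifier in the package.  It
follows the classic exact-test strategy for small-replicate RNA-seq count
data: columns are TMM-normalised, scaled to a common library size and summed
within group; the two group pseudo-sums are then compared conditionally on
their total under a negative-binomial model with a moderated dispersion.

The negative binomial is parameterised by mean mu and dispersion phi with
``variance = mu + phi * mu**2`` (phi = 0 recovers the Poisson).  A group of
``n`` i.i.d. NB(mu, phi) columns sums to NB(n*mu, phi/n), which is what the
exact test conditions on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

#: tolerance factor for "probability at most that of the observed outcome"
_P_TOL = 1.0 + 1e-7

#: dispersion used when no group has replication
FALLBACK_DISPERSION = 0.05

#: shrinkage strength of per-feature dispersions, in extra degrees of freedom
DEFAULT_PRIOR_DF = 10.0


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison between disjoint column sets.

    ``log2fc`` downstream is oriented as log2(group_a / group_b).
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.label!r}: empty column set")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label!r}: overlapping column sets")


def tmm_factors(counts, library_sizes) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors.

    Per column, against a reference column (the one whose upper-quartile
    count fraction is closest to the mean), a weighted mean of per-gene
    log2 ratios (M-values) is computed after trimming 30% of M-values and
    5% of A-values from each tail; weights are inverse asymptotic variances.
    Factors are rescaled to geometric mean 1, so composition bias moves a
    column's factor away from 1 while pure depth differences do not.
    """
    y = np.asarray(counts, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least two columns")
    n_col = y.shape[1]

    zero_cols = y.sum(axis=0) == 0
    if zero_cols.any():
        warnings.warn("all-zero column(s): TMM factor set to 1", RuntimeWarning)

    frac = y / libs[np.newaxis, :]
    uq = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(n_col)
    for j in range(n_col):
        if j == ref or zero_cols[j]:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], libs[j], libs[ref])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref,
              logratio_trim=0.3, sum_trim=0.05) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 10:
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method on two binomial proportions)
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (
        n_ref * ref[keep]
    )
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = m.size
    lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
    lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
    trim = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not trim.any() or n == 0:
        return 1.0
    f = np.sum(m[trim] / w[trim]) / np.sum(1.0 / w[trim])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def _cond_loglik(y: np.ndarray, group_idx: list[np.ndarray], phi) -> np.ndarray:
    """Conditional NB log-likelihood per feature, summed over groups.

    For a group of n equal-library columns with counts y_i and total z, the
    likelihood conditional on z depends only on phi:
    ``sum_i lgamma(y_i + r) - n*lgamma(r) + lgamma(n*r) - lgamma(z + n*r)``
    with r = 1/phi.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    r = 1.0 / phi  # (k,)
    ll = np.zeros((y.shape[0], r.size))
    for idx in group_idx:
        sub = y[:, idx]
        n = len(idx)
        z = sub.sum(axis=1)
        ll += (
            special.gammaln(sub[:, :, None] + r[None, None, :]).sum(axis=1)
            - n * special.gammaln(r)[None, :]
            + special.gammaln(n * r)[None, :]
            - special.gammaln(z[:, None] + n * r[None, :])
        )
    return ll


def estimate_dispersion(
    counts,
    groups,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> tuple[float, np.ndarray]:
    """Common and moderated per-feature NB dispersions.

    The common dispersion maximises the conditional NB log-likelihood summed
    over features, computed on library-size-equalised counts; groups without
    replication contribute nothing.  Per-feature dispersions maximise the
    feature's own conditional likelihood plus the across-feature average
    weighted by ``prior_df`` extra degrees of freedom, shrinking noisy
    feature-wise estimates toward the common value.

    Returns
    -------
    (common, per_feature)
        The common dispersion and an array of one moderated dispersion per
        feature.  Falls back to ``FALLBACK_DISPERSION`` with a warning when
        no group has at least two replicates.
    """
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    group_idx = [np.flatnonzero(groups == g) for g in labels]
    replicated = [idx for idx in group_idx if len(idx) >= 2]
    if not replicated:
        warnings.warn(
            "no replicated group: using fallback dispersion", RuntimeWarning
        )
        return FALLBACK_DISPERSION, np.full(y.shape[0], FALLBACK_DISPERSION)

    # equalise library sizes so the conditional likelihood applies
    libs = y.sum(axis=0)
    libs = np.where(libs <= 0, 1.0, libs)
    target = np.exp(np.mean(np.log(libs)))
    y_eq = np.rint(y * target / libs[np.newaxis, :])

    # keep features with some signal; all-zero rows carry no information
    informative = y_eq.sum(axis=1) > 0
    y_info = y_eq[informative]

    grid = np.concatenate([[1e-8], np.logspace(-4, 1.0, 61)])
    ll = _cond_loglik(y_info, replicated, grid)  # features x grid
    total = ll.sum(axis=0)
    common = float(grid[int(np.argmax(total))])
    # refine the common estimate between the neighbouring grid points
    i = int(np.argmax(total))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda lp: -float(
                _cond_loglik(y_info, replicated, np.exp(lp)).sum()
            ),
            bounds=(np.log(max(lo, 1e-10)), np.log(hi)),
            method="bounded",
        )
        common = float(np.exp(res.x))

    df_res = sum(len(idx) - 1 for idx in replicated)
    weight = prior_df / max(df_res, 1)
    shared = ll.mean(axis=0)  # average per-feature likelihood profile
    best = np.argmax(ll + weight * shared[np.newaxis, :], axis=1)
    per_feature = np.full(y.shape[0], common)
    per_feature[informative] = grid[best]
    return common, per_feature


def _nb_logpmf(k, r, mu):
    """log NB pmf with size r, mean mu (variance mu + mu^2/r)."""
    log_p = np.log(r) - np.log(r + mu)  # log prob of "success"
    log_q = np.log(mu) - np.log(r + mu)
    return (
        special.gammaln(k + r)
        - special.gammaln(r)
        - special.gammaln(k + 1)
        + r * log_p
        + k * log_q
    )


def nb_exact_test(sum_a, sum_b, n_a, n_b, phi) -> float:
    """Two-sided exact NB test of two group pseudo-sums.

    Conditions on the total ``s = sum_a + sum_b``: under the null, group
    totals are NB with means proportional to the group sizes ``n_a : n_b``
    and dispersions ``phi / n``; the p-value sums the conditional
    probabilities of every split of ``s`` whose probability does not exceed
    that of the observed split (within a 1 + 1e-7 relative tolerance).  With
    phi = 0 this reduces to the binomial two-tail.

    Counts are assumed already scaled to a common library size and summed
    within group.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    sum_a = int(round(sum_a))
    sum_b = int(round(sum_b))
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi < 1e-12:
        # Poisson totals: conditional distribution is binomial
        p = n_a / (n_a + n_b)
        logpmf = (
            special.gammaln(s + 1)
            - special.gammaln(k + 1)
            - special.gammaln(s - k + 1)
            + k * np.log(p)
            + (s - k) * np.log1p(-p)
        )
    else:
        mu = s / (n_a + n_b)
        logpmf = _nb_logpmf(k, n_a / phi, n_a * mu) + _nb_logpmf(
            s - k, n_b / phi, n_b * mu
        )
    logpmf = logpmf - special.logsumexp(logpmf)
    pmf = np.exp(logpmf)
    p_obs = pmf[sum_a]
    pval = float(pmf[pmf <= p_obs * _P_TOL].sum())
    return min(max(pval, np.nextafter(0, 1)), 1.0)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(k) = min(1, min_{j >= k} p_(j) * m / j)`` over the sorted
    p-values; order-preserving with respect to ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_de(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    contrast: Contrast,
    dispersion: float | None = None,
    prior_count: float = 0.5,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> pd.DataFrame:
    """Full two-group exact-test differential expression for one contrast.

    Pipeline: TMM factors -> effective library sizes -> per-column scaling to
    the geometric-mean effective size -> within-group pseudo-sums ->
    moderated dispersion -> conditional NB exact test -> BH adjustment.
    ``log2fc`` is log2 of the ratio of group mean CPMs, with ``prior_count``
    added to each group mean to avoid infinities.

    Parameters
    ----------
    counts : pandas.DataFrame
        Filtered integer counts (features x columns); must contain every
        contrast column.
    library_sizes : pandas.Series
        Per-column totals of the *unfiltered* table.
    contrast : Contrast
        ``log2fc`` > 0 means higher in ``group_a``.
    dispersion : float, optional
        Fix the dispersion instead of estimating it (used for tiny tracks).

    Returns
    -------
    pandas.DataFrame
        Columns ``log2fc``, ``pvalue``, ``fdr``, ``log2cpm`` indexed by
        feature id.
    """
    cols = list(contrast.group_a) + list(contrast.group_b)
    missing = [c for c in cols if c not in counts.columns]
    if missing:
        raise ValueError(f"contrast columns not in table: {missing}")
    y = counts[cols].to_numpy(dtype=float)
    libs = library_sizes[cols].to_numpy(dtype=float)

    factors = tmm_factors(y, libs)
    eff = libs * factors
    target = np.exp(np.mean(np.log(eff)))
    pseudo = y * target / eff[np.newaxis, :]

    n_a = len(contrast.group_a)
    n_b = len(contrast.group_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    groups = np.array(["a"] * n_a + ["b"] * n_b)

    if dispersion is None:
        _, phi_g = estimate_dispersion(
            np.rint(pseudo), groups, prior_df=prior_df
        )
    else:
        if dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        phi_g = np.full(y.shape[0], float(dispersion))

    sums_a = np.rint(pseudo[:, idx_a].sum(axis=1)).astype(np.int64)
    sums_b = np.rint(pseudo[:, idx_b].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            nb_exact_test(sa, sb, n_a, n_b, phi)
            for sa, sb, phi in zip(sums_a, sums_b, phi_g)
        ]
    )

    cpm_mat = y * 1e6 / eff[np.newaxis, :]
    mean_a = cpm_mat[:, idx_a].mean(axis=1)
    mean_b = cpm_mat[:, idx_b].mean(axis=1)
    lfc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)
    log2cpm = np.log2(0.5 * (mean_a + mean_b) + prior_count)

    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "log2cpm": log2cpm,
        },
        index=counts.index,
    )
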