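"""Parent-of-origin (imprinting) detection from reciprocal allelic fractions.

In the BN hybrid (C. briggsae father x C. nigoni mother) the C. briggsae
allele is paternal; in the reciprocal NB hybrid it is maternal.  A gene is
imprinted when the same parent-of-origin allele dominates (>= 75% of the
pair's expression by default) in *both* crossing directions — a skew that
cannot be explained by cis divergence, which would favour the same species'
allele in both hybrids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 0.75
DEFAULT_MIN_TOTAL_CPM = 5.0


def allele_fraction(cpm_cbr, cpm_cni, min_total: float = DEFAULT_MIN_TOTAL_CPM):
    """Fraction of C. briggsae allelic expression, or NaN below the floor.

    ``cpm_cbr / (cpm_cbr + cpm_cni)`` where the combined expression reaches
    ``min_total`` CPM; pairs below the floor are no-calls (NaN) because
    fractions of near-zero counts are noise.
    """
    a = np.asarray(cpm_cbr, dtype=float)
    b = np.asarray(cpm_cni, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("CPM values must be non-negative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total >= min_total, a / total, np.nan)
    return float(frac) if np.isscalar(cpm_cbr) else frac


def call_imprinting(f_bn, f_nb, cutoff: float = DEFAULT_CUTOFF):
    """Imprint status from the Cbr-allele fractions in BN and NB.

    ``maternal`` when the maternal allele holds at least ``cutoff`` of the
    expression in both hybrids — i.e. the Cni allele in BN
    (``1 - f_bn >= cutoff``) and the Cbr allele in NB (``f_nb >= cutoff``);
    ``paternal`` symmetrically; otherwise (including no-call fractions)
    ``none``.
    """
    scalar = np.isscalar(f_bn)
    f_bn = np.atleast_1d(np.asarray(f_bn, dtype=float))
    f_nb = np.atleast_1d(np.asarray(f_nb, dtype=float))
    callable_ = np.isfinite(f_bn) & np.isfinite(f_nb)
    maternal = callable_ & (1 - f_bn >= cutoff) & (f_nb >= cutoff)
    paternal = callable_ & (f_bn >= cutoff) & (1 - f_nb >= cutoff)
    out = np.select(
        [maternal, paternal],
        np.array(["maternal", "paternal"], dtype=object),
        default="none",
    )
    return out[0] if scalar else out


def parental_leaning(f_bn, f_nb):
    """Overall maternal/paternal leaning from the mean maternal fraction.

    The maternal-allele fraction is ``1 - f_bn`` in BN and ``f_nb`` in NB;
    their mean above 0.5 leans maternal, below leans paternal, equality
    (within 1e-12) is balanced.
    """
    scalar = np.isscalar(f_bn)
    f_bn = np.atleast_1d(np.asarray(f_bn, dtype=float))
    f_nb = np.atleast_1d(np.asarray(f_nb, dtype=float))
    mean_maternal = ((1 - f_bn) + f_nb) / 2.0
    out = np.select(
        [mean_maternal > 0.5 + 1e-12, mean_maternal < 0.5 - 1e-12],
        np.array(["maternal", "paternal"], dtype=object),
        default="balanced",
    )
    out = np.where(
        np.isfinite(mean_maternal), out, np.array("none", dtype=object)
    )
    return out[0] if scalar else out


def call_table(
    mean_cpm: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    min_total: float = DEFAULT_MIN_TOTAL_CPM,
) -> pd.DataFrame:
    """Imprint calls for every pair from group-mean haplotype CPMs.

    ``mean_cpm`` must hold columns ``BN_cbr``, ``BN_cni``, ``NB_cbr``,
    ``NB_cni`` (replicate-averaged CPM per group), indexed by pair id.
    """
    f_bn = allele_fraction(
        mean_cpm["BN_cbr"].to_numpy(), mean_cpm["BN_cni"].to_numpy(), min_total
    )
    f_nb = allele_fraction(
        mean_cpm["NB_cbr"].to_numpy(), mean_cpm["NB_cni"].to_numpy(), min_total
    )
    return pd.DataFrame(
        {
            "f_cbr_BN": f_bn,
            "f_cbr_NB": f_nb,
            "status": call_imprinting(f_bn, f_nb, cutoff),
            "leaning": parental_leaning(f_bn, f_nb),
            "no_call": ~(np.isfinite(f_bn) & np.isfinite(f_nb)),
        },
        index=mean_cpm.index,
    )
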