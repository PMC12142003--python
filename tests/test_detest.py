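import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridase import detest
from hybridase.detest import (
    Contrast,
    bh_fdr,
    estimate_dispersion,
    nb_exact_test,
    run_de,
    tmm_factors,
)


def bh_oracle(p):
    """Brute-force step-up definition: q_i = min over j with
    p_(j) >= p_(i) of min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    sp = np.sort(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        q[i] = min(
            min(1.0, sp[j] * m / (j + 1)) for j in range(m) if sp[j] >= pi
        )
    return q


def nb_exact_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Independent enumeration via scipy's NB/binomial pmf."""
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi == 0:
        pmf = stats.binom.pmf(k, s, n_a / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        pmf = stats.nbinom.pmf(k, r_a, r_a / (r_a + n_a * mu)) * stats.nbinom.pmf(
            s - k, r_b, r_b / (r_b + n_b * mu)
        )
        pmf = pmf / pmf.sum()
    return float(pmf[pmf <= pmf[sum_a] * (1 + 1e-7)].sum())


class TestTmmFactors:
    def test_identical_columns_unity(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, size=500).astype(float)
        y = np.column_stack([col, col])
        assert np.allclose(tmm_factors(y, y.sum(axis=0)), 1.0)

    def test_pure_depth_difference_unity(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 1000, size=500).astype(float)
        y = np.column_stack([col, 2 * col])
        assert np.allclose(tmm_factors(y, y.sum(axis=0)), 1.0, atol=1e-6)

    def test_composition_bias_shrinks_factor(self):
        """5% of genes 100x inflated in column B drags B's factor below 1,
        matching the direction of a no-trim weighted-mean oracle."""
        rng = np.random.default_rng(2)
        a = rng.integers(50, 500, size=1000).astype(float)
        b = a.copy()
        b[:50] *= 100
        y = np.column_stack([a, b])
        libs = y.sum(axis=0)
        factors = tmm_factors(y, libs)
        assert factors[1] < 1.0
        # direction oracle: untrimmed mean log-ratio of B vs A
        m = np.log2((b / libs[1]) / (a / libs[0]))
        assert np.sign(np.log2(factors[1] / factors[0])) == np.sign(m.mean())

    def test_all_zero_column_warns_unity(self):
        y = np.column_stack([np.arange(1, 101, dtype=float), np.zeros(100)])
        with pytest.warns(RuntimeWarning):
            factors = tmm_factors(y, np.array([y[:, 0].sum(), 1.0]))
        assert factors[1] == pytest.approx(1.0)


class TestEstimateDispersion:
    def test_poisson_truth_gives_small_common(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, size=2000)
        y = rng.poisson(mu[:, None], size=(2000, 6))
        common, _ = estimate_dispersion(y, ["a"] * 3 + ["b"] * 3)
        assert common <= 0.01

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(4)
        phi = 0.2
        mu = rng.uniform(50, 500, size=2000)
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        common, _ = estimate_dispersion(y, ["a"] * 3 + ["b"] * 3)
        assert 0.15 <= common <= 0.25

    def test_single_replicate_fallback(self):
        y = np.array([[5, 9], [100, 80]])
        with pytest.warns(RuntimeWarning, match="fallback"):
            common, per = estimate_dispersion(y, ["a", "b"])
        assert common == 0.05 and (per == 0.05).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersion(np.array([[-1, 2, 3, 4]]), ["a", "a", "b", "b"])


class TestNbExactTest:
    def test_symmetric_split_is_mode(self):
        assert nb_exact_test(5, 5, 1, 1, 0.0) == pytest.approx(1.0)

    def test_extreme_split_binomial_two_tail(self):
        assert nb_exact_test(0, 10, 1, 1, 0.0) == pytest.approx(2 / 1024)

    def test_matches_enumeration_oracle_with_dispersion(self):
        p = nb_exact_test(2, 14, 2, 2, 0.1)
        assert p == pytest.approx(nb_exact_oracle(2, 14, 2, 2, 0.1), abs=1e-12)

    @pytest.mark.parametrize("sa,sb", [(0, 20), (3, 17), (8, 12), (10, 10)])
    def test_phi_zero_equals_binomial_two_tail(self, sa, sb):
        s = sa + sb
        k = np.arange(s + 1)
        pmf = stats.binom.pmf(k, s, 0.5)
        expected = pmf[pmf <= pmf[sa] * (1 + 1e-7)].sum()
        assert nb_exact_test(sa, sb, 2, 2, 0.0) == pytest.approx(
            expected, abs=1e-9
        )

    def test_unequal_group_sizes_match_oracle(self):
        for phi in (0.0, 0.05, 0.3):
            p = nb_exact_test(30, 11, 3, 2, phi)
            assert p == pytest.approx(
                nb_exact_oracle(30, 11, 3, 2, phi), abs=1e-10
            )

    def test_zero_total_is_one(self):
        assert nb_exact_test(0, 0, 2, 2, 0.1) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 1, 1, 1, -0.1)


class TestBhFdr:
    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200))
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.random(500)
        reference = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), reference, atol=1e-12)


def _nb_counts(rng, mu, phi, n_cols):
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu[:, None]), size=(mu.size, n_cols))


class TestRunDe:
    def test_self_contrast_is_null(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(50, 500, size=300)
        col = rng.poisson(mu)
        counts = pd.DataFrame(
            np.column_stack([col, col, col, col]),
            columns=["a1", "a2", "b1", "b2"],
        )
        de = run_de(
            counts,
            counts.sum(axis=0).astype(float),
            Contrast(("a1", "a2"), ("b1", "b2"), "self"),
        )
        assert (de["log2fc"].abs() < 1e-9).all()
        assert (de["fdr"] > 0.9).all()

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(20, 800, size=200)
        counts = pd.DataFrame(
            _nb_counts(rng, mu, 0.05, 6),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        libs = counts.sum(axis=0).astype(float)
        de1 = run_de(counts, libs, Contrast(("a1", "a2", "a3"), ("b1", "b2", "b3")))
        de2 = run_de(counts, libs, Contrast(("a3", "a1", "a2"), ("b2", "b3", "b1")))
        assert np.allclose(de1["pvalue"], de2["pvalue"])
        assert np.allclose(de1["log2fc"], de2["log2fc"])

    def test_power_at_fourfold_change(self):
        """A true 4-fold change at phi = 0.05 with 3v3 replicates is
        recovered (FDR < 0.05, log2fc in [1.5, 2.5]) in nearly every run."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            mu = rng.uniform(50, 500, size=200)
            mu_b = mu.copy()
            mu_b[0] = mu[0] * 4  # planted gene
            y = np.column_stack(
                [_nb_counts(rng, mu_b, 0.05, 3), _nb_counts(rng, mu, 0.05, 3)]
            )
            counts = pd.DataFrame(y, columns=[f"a{i}" for i in range(3)]
                                  + [f"b{i}" for i in range(3)])
            de = run_de(
                counts,
                counts.sum(axis=0).astype(float),
                Contrast(("a0", "a1", "a2"), ("b0", "b1", "b2")),
            )
            row = de.iloc[0]
            if row["fdr"] < 0.05 and 1.5 <= row["log2fc"] <= 2.5:
                hits += 1
        assert hits / n_rep >= 0.9
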