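import numpy as np
import pandas as pd
import pytest

from hybridase import orthology


def _models(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome", "start", "end", "isoform_id",
                 "protein_length"],
    )


class TestSelectRepresentatives:
    def test_longest_overlapping_gene_wins(self):
        models = _models([
            ("gA", "I", 100, 1000, "gA.1", 300),
            ("gB", "I", 500, 1700, "gB.1", 400),
        ])
        reps = orthology.select_representatives(models)
        assert list(reps["gene_id"]) == ["gB"]

    def test_non_overlapping_genes_both_kept(self):
        models = _models([
            ("gA", "I", 100, 400, "gA.1", 100),
            ("gB", "I", 500, 900, "gB.1", 100),
            ("gC", "II", 100, 400, "gC.1", 100),
        ])
        reps = orthology.select_representatives(models)
        assert sorted(reps["gene_id"]) == ["gA", "gB", "gC"]

    def test_span_tie_breaks_lexicographically(self):
        """Verified against an exhaustive pairwise check: equal spans keep
        the lexicographically smaller gene id."""
        models = _models([
            ("gB", "I", 100, 700, "gB.1", 100),
            ("gA", "I", 100, 700, "gA.1", 100),
        ])
        reps = orthology.select_representatives(models)
        assert list(reps["gene_id"]) == ["gA"]
        # pairwise oracle over every ordering
        for first, second in (("gA", "gB"), ("gB", "gA")):
            m = _models([
                (first, "I", 0, 10, f"{first}.1", 5),
                (second, "I", 0, 10, f"{second}.1", 5),
            ])
            assert list(orthology.select_representatives(m)["gene_id"]) == ["gA"]

    def test_longest_isoform_is_representative(self):
        models = _models([
            ("gA", "I", 100, 900, "gA.1", 150),
            ("gA", "I", 100, 900, "gA.2", 420),
        ])
        reps = orthology.select_representatives(models)
        assert reps.loc[0, "isoform_id"] == "gA.2"

    def test_missing_coordinates_rejected(self):
        models = _models([("gA", "I", np.nan, 900, "gA.1", 100)])
        with pytest.raises(ValueError, match="coordinates"):
            orthology.select_representatives(models)


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["query", "subject", "score", "e_value", "qlen", "slen"]
    )


def _rbh_oracle(forward, reverse, e_cutoff=1e-4):
    """Brute-force mutual-best enumeration over all (a, b) combinations."""
    fwd = forward[forward["e_value"] < e_cutoff]
    rev = reverse[reverse["e_value"] < e_cutoff]
    pairs = set()
    for a in fwd["query"].unique():
        for b in fwd.loc[fwd["query"] == a, "subject"].unique():
            fa = fwd[fwd["query"] == a]
            top_a = fa["score"].max()
            a_best = set(fa.loc[fa["score"] == top_a, "subject"])
            rb = rev[rev["query"] == b]
            if rb.empty:
                continue
            top_b = rb["score"].max()
            b_best = set(rb.loc[rb["score"] == top_b, "subject"])
            if a_best == {b} and b_best == {a}:
                pairs.add((a, b))
    return pairs


class TestReciprocalBestHits:
    def test_mutual_best_pair(self):
        fwd = _hits([("A1", "B1", 200.0, 1e-50, 100, 100)])
        rev = _hits([("B1", "A1", 199.0, 1e-48, 100, 100)])
        pairs = orthology.reciprocal_best_hits(fwd, rev)
        assert list(pairs.itertuples(index=False, name=None)) == [("A1", "B1")]

    def test_mutuality_violation_excludes_both(self):
        fwd = _hits([
            ("A1", "B1", 200.0, 1e-50, 100, 100),
            ("A2", "B1", 150.0, 1e-30, 100, 100),
            ("A2", "B2", 300.0, 1e-60, 100, 100),
        ])
        rev = _hits([
            ("B1", "A2", 210.0, 1e-52, 100, 100),
            ("B1", "A1", 180.0, 1e-40, 100, 100),
        ])
        pairs = orthology.reciprocal_best_hits(fwd, rev)
        assert "A1" not in set(pairs["query"])
        assert "B1" not in set(pairs["subject"])

    def test_score_tie_excludes_query(self):
        fwd = _hits([
            ("A1", "B1", 200.0, 1e-50, 100, 100),
            ("A1", "B2", 200.0, 1e-50, 100, 100),
        ])
        rev = _hits([("B1", "A1", 200.0, 1e-50, 100, 100)])
        assert orthology.reciprocal_best_hits(fwd, rev).empty

    def test_empty_tables_give_empty_output(self):
        empty = _hits([])
        assert orthology.reciprocal_best_hits(empty, empty).empty

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a_ids = [f"A{i}" for i in range(5)]
        b_ids = [f"B{i}" for i in range(5)]
        # discrete scores make ties likely
        fwd = _hits([
            (a, b, float(rng.integers(1, 6)), 1e-10, 100, 100)
            for a in a_ids for b in b_ids if rng.random() < 0.7
        ])
        rev = _hits([
            (b, a, float(rng.integers(1, 6)), 1e-10, 100, 100)
            for b in b_ids for a in a_ids if rng.random() < 0.7
        ])
        got = set(
            orthology.reciprocal_best_hits(fwd, rev).itertuples(
                index=False, name=None
            )
        )
        assert got == _rbh_oracle(fwd, rev)

    def test_symmetry_under_table_swap(self):
        rng = np.random.default_rng(42)
        fwd = _hits([
            (f"A{i}", f"B{j}", float(rng.integers(1, 50)), 1e-10, 100, 100)
            for i in range(6) for j in range(6)
        ])
        rev = _hits([
            (f"B{j}", f"A{i}", float(rng.integers(1, 50)), 1e-10, 100, 100)
            for i in range(6) for j in range(6)
        ])
        ab = set(
            orthology.reciprocal_best_hits(fwd, rev).itertuples(
                index=False, name=None
            )
        )
        ba = set(
            orthology.reciprocal_best_hits(rev, fwd).itertuples(
                index=False, name=None
            )
        )
        assert ab == {(a, b) for b, a in ba}

    def test_no_gene_appears_twice(self):
        rng = np.random.default_rng(7)
        fwd = _hits([
            (f"A{i}", f"B{j}", float(rng.integers(1, 9)), 1e-10, 100, 100)
            for i in range(8) for j in range(8)
        ])
        rev = _hits([
            (f"B{j}", f"A{i}", float(rng.integers(1, 9)), 1e-10, 100, 100)
            for i in range(8) for j in range(8)
        ])
        pairs = orthology.reciprocal_best_hits(fwd, rev)
        assert pairs["query"].is_unique and pairs["subject"].is_unique


class TestGroupOneToN:
    def test_all_genes_to_shared_term(self):
        hits = _hits([
            ("g1", "T", 100.0, 1e-20, 50, 50),
            ("g2", "T", 90.0, 1e-18, 50, 50),
            ("g3", "T", 80.0, 1e-15, 50, 50),
        ])
        assert orthology.group_one_to_n(hits) == {"T": ["g1", "g2", "g3"]}

    def test_best_hit_assignment_is_exclusive(self):
        hits = _hits([
            ("g1", "T1", 200.0, 1e-40, 50, 50),
            ("g1", "T2", 150.0, 1e-30, 50, 50),
        ])
        assert orthology.group_one_to_n(hits) == {"T1": ["g1"]}

    def test_group_count_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(400):
            for t in rng.choice(60, size=rng.integers(1, 4), replace=False):
                rows.append((f"g{i}", f"T{t}", float(rng.integers(10, 500)),
                             1e-10, 50, 50))
        hits = _hits(rows)
        groups = orthology.group_one_to_n(hits)
        # one-line grouping oracle: count distinct argmax terms
        oracle = (
            hits.sort_values(["score", "e_value", "subject"],
                             ascending=[False, True, True])
            .groupby("query")["subject"].first().nunique()
        )
        assert len(groups) == oracle
        members = [g for v in groups.values() for g in v]
        assert len(members) == len(set(members))
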