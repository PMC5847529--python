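from itertools import combinations

import numpy as np
import pytest

from chicpeaks.comparison import (
    PeakSet,
    jaccard,
    jaccard_dendrogram,
    locus_count_tests,
    peak_overlap_sets,
    permutation_sharing_test,
)

import pandas as pd


def _ps(name, peaks, universe):
    return PeakSet(name, frozenset(peaks), frozenset(universe))


class TestVenn:
    def test_basic_overlap(self):
        counts = peak_overlap_sets(
            [_ps("A", {"x", "y"}, {"x", "y", "z"}), _ps("B", {"y", "z"}, {"x", "y", "z"})]
        )
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert counts[frozenset({"A", "B"})] == 1

    def test_identical_sets_all_in_intersection(self):
        counts = peak_overlap_sets(
            [_ps("A", {"x", "y"}, {"x", "y"}), _ps("B", {"x", "y"}, {"x", "y"})]
        )
        assert counts[frozenset({"A", "B"})] == 2
        assert counts[frozenset({"A"})] == 0

    def test_disjoint_sets(self):
        counts = peak_overlap_sets(
            [_ps("A", {"x"}, {"x", "y"}), _ps("B", {"y"}, {"x", "y"})]
        )
        assert counts[frozenset({"A", "B"})] == 0

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(0)
        universe = list(range(40))
        sets = [
            _ps(f"L{i}", rng.choice(universe, 10, replace=False).tolist(), universe)
            for i in range(3)
        ]
        counts = peak_overlap_sets(sets)
        union = set().union(*[s.peaks for s in sets])
        assert sum(counts.values()) == len(union)


def exhaustive_all_shared_p(universes, peak_sizes, observed):
    """Exact P(shared-by-all >= observed) by enumerating every subset draw."""
    pools = [
        list(combinations(sorted(u), k)) for u, k in zip(universes, peak_sizes)
    ]
    total = 0
    hits = 0
    from itertools import product

    for picks in product(*pools):
        total += 1
        inter = set(picks[0])
        for p in picks[1:]:
            inter &= set(p)
        if len(inter) >= observed:
            hits += 1
    return hits / total


def exhaustive_exclusive_p(universes, peak_sizes, focal_idx, observed):
    pools = [list(combinations(sorted(u), k)) for u, k in zip(universes, peak_sizes)]
    from itertools import product

    total = 0
    hits = 0
    for picks in product(*pools):
        total += 1
        focal = set(picks[focal_idx])
        others = set().union(*[set(p) for i, p in enumerate(picks) if i != focal_idx])
        if len(focal - others) >= observed:
            hits += 1
    return hits / total


class TestPermutationSharing:
    def test_forced_overlap_p_one(self):
        sets = [_ps("A", {1}, {1}), _ps("B", {1}, {1})]
        res = permutation_sharing_test(sets, n_perm=200, seed=0)
        assert res.permutation_p == 1.0

    def test_disjoint_universes_p_one(self):
        sets = [_ps("A", {1}, {1, 2}), _ps("B", {3}, {3, 4})]
        res = permutation_sharing_test(sets, n_perm=200, seed=0)
        assert res.observed_shared == 0 and res.permutation_p == 1.0

    def test_matches_exhaustive_enumeration_two_lines(self):
        universe = set(range(10))
        sets = [_ps("A", {0, 1}, universe), _ps("B", {0, 1}, universe)]
        n_perm = 10_000
        res = permutation_sharing_test(sets, n_perm=n_perm, seed=3)
        exact = exhaustive_all_shared_p([universe] * 2, [2, 2], res.observed_shared)
        mc_se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.permutation_p - exact) <= 3 * mc_se + 2 / n_perm

    def test_exclusive_mode_matches_enumeration(self):
        uA = set(range(8))
        uB = set(range(4, 12))  # partial overlap of universes
        sets = [_ps("A", {0, 1, 5}, uA), _ps("B", {5, 6}, uB)]
        n_perm = 10_000
        res = permutation_sharing_test(sets, n_perm=n_perm, seed=4, mode="exclusive", focal="A")
        exact = exhaustive_exclusive_p([uA, uB], [3, 2], 0, res.observed_shared)
        mc_se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.permutation_p - exact) <= 3 * mc_se + 2 / n_perm

    def test_seed_required_and_reproducible(self):
        sets = [_ps("A", {0, 1}, set(range(10))), _ps("B", {0, 2}, set(range(10)))]
        with pytest.raises(ValueError):
            permutation_sharing_test(sets, n_perm=10)
        r1 = permutation_sharing_test(sets, n_perm=500, seed=9)
        r2 = permutation_sharing_test(sets, n_perm=500, seed=9)
        assert r1.permutation_p == r2.permutation_p


class TestJaccard:
    def test_identity_disjoint_half(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0
        assert jaccard({1}, {2}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_empty_sets_convention(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 1.0

    def test_metric_properties_on_random_sets(self):
        rng = np.random.default_rng(5)
        sets = [set(rng.choice(30, rng.integers(1, 15), replace=False).tolist()) for _ in range(8)]
        for A in sets:
            for B in sets:
                assert abs(jaccard(A, B) - jaccard(B, A)) < 1e-15
                assert 0 <= jaccard(A, B) <= 1
        # triangle inequality for the Jaccard distance 1 - J
        for A in sets:
            for B in sets:
                for C in sets:
                    dAB = 1 - jaccard(A, B)
                    dBC = 1 - jaccard(B, C)
                    dAC = 1 - jaccard(A, C)
                    assert dAC <= dAB + dBC + 1e-12

    def test_dendrogram_newick_parses(self):
        import dendropy

        universe = set(range(30))
        sets = [
            _ps("T47D", set(range(10)), universe),
            _ps("ZR751", set(range(2, 12)), universe),
            _ps("GM", set(range(20, 30)), universe),
        ]
        dm, newick = jaccard_dendrogram(sets)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = {t.label for t in tree.taxon_namespace}
        assert labels == {"T47D", "ZR751", "GM"}
        # the two similar lines cluster together
        assert dm.loc["T47D", "ZR751"] < dm.loc["T47D", "GM"]


class TestLocusTests:
    def _table(self, groups):
        rows = []
        for cl, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"locus_id": f"L{i}", "cell_line": cl, "n_peaks": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        table = self._table({"A": [1, 2, 3], "B": [1, 2, 3], "C": [1, 2, 3]})
        out = locus_count_tests(table)
        kw = out[out["test"] == "kruskal_wallis"].iloc[0]
        assert kw["statistic"] < 1e-9 and kw["p"] > 0.99

    def test_exact_mann_whitney_separated_groups(self):
        table = self._table({"A": [1, 2, 3], "B": [4, 5, 6]})
        out = locus_count_tests(table, contrasts=[(["A"], ["B"])])
        mw = out[out["test"] == "mann_whitney"].iloc[0]
        assert mw["statistic"] == 0.0
        assert abs(mw["p"] - 0.1) < 1e-12

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        table = self._table(
            {"A": rng.poisson(5, 20), "B": rng.poisson(5, 20), "C": rng.poisson(40, 20)}
        )
        out = locus_count_tests(table)
        assert out[out["test"] == "kruskal_wallis"]["p"].iloc[0] < 0.01

    def test_empty_group_rejected(self):
        table = self._table({"A": [1, 2]})
        with pytest.raises(ValueError):
            locus_count_tests(table)
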