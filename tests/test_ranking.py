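"""Feature-ranker oracles: exhaustive rank-sum enumeration, direct
sum-of-squares, hand entropy arithmetic, exhaustive CFS merits, and
brute-force ReliefF neighbours."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from subtypebench.ranking import (
    bwr_scores,
    cfs_merit,
    discretize,
    filter_correlated,
    mutual_information,
    rank_bwr,
    rank_cfs,
    rank_features,
    rank_infogain,
    rank_relief,
    rank_wmw,
    relief_weights,
    symmetrical_uncertainty,
)


def exact_wmw_pvalue(a, b):
    """Two-sided rank-sum p-value by exhaustive enumeration of all
    C(n_a + n_b, n_a) assignments of the pooled ranks (tie-free data)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(pooled)
    stats = []
    for combo in itertools.combinations(range(1, n + 1), len(a)):
        stats.append(sum(combo))
    mean = np.mean(stats)
    observed_dev = abs(observed - mean)
    extreme = sum(1 for s in stats if abs(s - mean) >= observed_dev - 1e-12)
    return extreme / len(stats)


class TestWMW:
    def test_exact_p_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert exact_wmw_pvalue(a, b) == pytest.approx(0.1)
        X = pd.DataFrame({"f": a + b})
        y = [1, 1, 1, 0, 0, 0]
        ranked = rank_wmw(X, y)
        assert ranked.table["score"][0] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_fixtures_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 8), rng.integers(3, 8)
        vals = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
        a, b = list(vals[:na]), list(vals[na:])
        X = pd.DataFrame({"f": a + b})
        y = [1] * na + [0] * nb
        got = rank_wmw(X, y).table["score"][0]
        assert got == pytest.approx(exact_wmw_pvalue(a, b), abs=1e-12)

    def test_constant_feature_p1_and_last(self):
        X = pd.DataFrame({"a": [0, 0, 1, 1, 2, 2], "c": [5.0] * 6})
        y = [1, 1, 1, 0, 0, 0]
        ranked = rank_wmw(X, y)
        assert ranked.feature_ids[-1] == "c"
        assert ranked.table.set_index("feature_id").loc["c", "score"] == 1.0

    def test_separating_feature_first(self):
        X = pd.DataFrame({"noise": [5.0] * 6, "sep": [1, 2, 3, 10, 11, 12]})
        ranked = rank_wmw(X, [0, 0, 0, 1, 1, 1])
        assert ranked.feature_ids[0] == "sep"

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            rank_wmw(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 1, 0
        r1 = rank_wmw(X, y)
        r2 = rank_wmw(np.exp(X) * 3 + 1, y)
        assert r1.feature_ids == r2.feature_ids

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        y = np.array([0, 1] * 10)
        perm = rng.permutation(20)
        assert (
            rank_wmw(X, y).feature_ids
            == rank_wmw(X.iloc[perm].reset_index(drop=True), y[perm]).feature_ids
        )


class TestFilterCorrelated:
    def test_duplicate_removed(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        X = pd.DataFrame({"a": v, "b": v.copy(), "c": rng.normal(size=20)})
        y = (v > 0).astype(int)
        kept = filter_correlated(X, rank_wmw(X, y))
        assert "b" not in kept.feature_ids or "a" not in kept.feature_ids
        assert len(kept.feature_ids) == 2

    def test_uncorrelated_unchanged(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 50)
        y[:2], y[-2:] = 1, 0
        base = rank_wmw(X, y)
        kept = filter_correlated(X, base)
        assert kept.feature_ids == base.feature_ids

    def test_greedy_rule_matches_bruteforce(self):
        """Six features with a planted correlation structure: the kept set
        must equal a direct simulation of the greedy keep-against-kept rule."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=40)
        X = pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.1, 40),          # ~ base
                "b": base + rng.normal(0, 0.1, 40),          # ~ base
                "c": rng.normal(size=40),
                "d": -base + rng.normal(0, 0.1, 40),         # anti-correlated
                "e": rng.normal(size=40),
                "f": base + rng.normal(0, 2.0, 40),          # weakly correlated
            }
        )
        y = (base > 0).astype(int)
        ranking = rank_wmw(X, y)
        kept = filter_correlated(X, ranking, r_max=0.75).feature_ids
        expected = []
        for f in ranking.feature_ids:
            if all(
                abs(np.corrcoef(X[f], X[g])[0, 1]) <= 0.75 for g in expected
            ):
                expected.append(f)
        assert kept == expected
        assert kept[0] == ranking.feature_ids[0]  # top feature never removed


class TestBWR:
    def test_equal_class_means_zero(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
        assert bwr_scores(X.to_numpy(), np.array([0, 0, 1, 1]))[0] == 0.0

    def test_matches_direct_sum_of_squares(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        grand = x.mean()
        between = sum(
            (y == c).sum() * (x[y == c].mean() - grand) ** 2 for c in (0, 1)
        )
        within = sum(((x[y == c] - x[y == c].mean()) ** 2).sum() for c in (0, 1))
        expected = between / within
        got = bwr_scores(x.reshape(-1, 1), y)[0]
        assert got == pytest.approx(expected, rel=1e-12)
        # class means 0.5 and 2.5, grand 1.5: between = 2 * 4 * 1^2 = 8,
        # within = 2 * 4 * 0.25 = 2
        assert expected == pytest.approx(8.0 / 2.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 1))
        y = np.array([0, 1] * 10)
        s1 = bwr_scores(x, y)[0]
        s2 = bwr_scores(x * 7.3 - 2.0, y)[0]
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_zero_within_is_inf_ranked_first(self):
        X = pd.DataFrame({"pure": [0.0, 0.0, 1.0, 1.0], "n": [0.1, 0.9, 0.2, 0.8]})
        ranked = rank_bwr(X, [0, 0, 1, 1])
        assert ranked.feature_ids[0] == "pure"
        assert np.isinf(ranked.table["score"][0])


class TestInfoGain:
    def test_feature_equal_to_labels_scores_class_entropy(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        X = pd.DataFrame({"f": y.astype(float)})
        score = rank_infogain(X, y).table["score"][0]
        assert score == pytest.approx(-(0.5 * math.log(0.5)) * 2)

    def test_constant_feature_zero(self):
        X = pd.DataFrame({"f": [1.0] * 6})
        assert rank_infogain(X, [1, 1, 1, 0, 0, 0]).table["score"][0] == pytest.approx(0.0)

    def test_2x2_table_matches_hand_entropy(self):
        """Counts (a,pCR)=3, (a,no)=1, (b,pCR)=1, (b,no)=3."""
        X = pd.DataFrame({"f": ["a"] * 4 + ["b"] * 4})
        y = [1, 1, 1, 0, 1, 0, 0, 0]
        hy = -(0.5 * math.log(0.5)) * 2
        h_cond = 0.5 * (-(0.75 * math.log(0.75) + 0.25 * math.log(0.25))) * 2
        expected = hy - h_cond
        got = rank_infogain(X, y).table["score"][0]
        assert got == pytest.approx(expected, abs=1e-12)


class TestCFS:
    def test_single_feature_merit_is_class_correlation(self):
        y = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        X = pd.DataFrame({"f": y.astype(float)})
        ranked = rank_cfs(X, y)
        su = symmetrical_uncertainty(y, y)
        assert ranked.table["score"][0] == pytest.approx(su)

    def test_copy_of_label_ranked_first_redundancy_penalized(self):
        """Exhaustive merit evaluation over all subsets of the 3 features is
        the oracle for what forward selection should do."""
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 40)
        y[:3], y[-3:] = 1, 0
        X = pd.DataFrame(
            {
                "copy": y.astype(float),
                "dup": y.astype(float),
                "noise": rng.integers(0, 2, 40).astype(float),
            }
        )
        names = sorted(X.columns)
        ycodes = y.astype(int)
        su_cf = [symmetrical_uncertainty(X[f].to_numpy().astype(int), ycodes) for f in names]
        su_ff = {}
        for i in range(3):
            for j in range(i + 1, 3):
                su_ff[(i, j)] = symmetrical_uncertainty(
                    X[names[i]].to_numpy().astype(int), X[names[j]].to_numpy().astype(int)
                )
        merits = {
            subset: cfs_merit(su_cf, su_ff, list(subset))
            for r in (1, 2, 3)
            for subset in itertools.combinations(range(3), r)
        }
        best_single = max(merits[(i,)] for i in range(3))
        ranked = rank_cfs(X, y)
        assert ranked.feature_ids[0] == "copy"  # lexicographic among the two copies
        assert merits[(names.index("copy"),)] == pytest.approx(best_single)
        # adding the duplicate never improves the merit of {copy}
        i_copy, i_dup = names.index("copy"), names.index("dup")
        pair = tuple(sorted((i_copy, i_dup)))
        assert merits[pair] <= merits[(i_copy,)] + 1e-12

    def test_all_constant_features_rank_by_id(self):
        X = pd.DataFrame({"b": [1.0] * 6, "a": [2.0] * 6, "c": [3.0] * 6})
        ranked = rank_cfs(X, [1, 1, 1, 0, 0, 0])
        assert ranked.feature_ids == ["a", "b", "c"]

    def test_all_features_present_exactly_once(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.integers(0, 3, size=(30, 5)).astype(float), columns=list("abcde"))
        y = rng.integers(0, 2, 30)
        y[:2], y[-2:] = 1, 0
        ranked = rank_cfs(X, y)
        assert sorted(ranked.feature_ids) == list("abcde")


class TestRelief:
    def test_label_copy_attains_max_weight(self):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        X = pd.DataFrame({"label": y.astype(float), "const": np.ones(8)})
        ranked = rank_relief(X, y, kinds={"label": "binary", "const": "binary"}, k_neighbors=3)
        assert ranked.feature_ids[0] == "label"
        w = ranked.table.set_index("feature_id")["score"]
        assert w["label"] == pytest.approx(1.0)  # every miss differs, every hit agrees

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"c": np.ones(10), "r": rng.normal(size=10)})
        y = np.array([0, 1] * 5)
        w = relief_weights(X, y, kinds={"c": "continuous", "r": "continuous"}, k_neighbors=2)
        assert w["c"] == 0.0

    def test_matches_bruteforce_k1(self):
        """8-sample, 3-feature fixture at k=1 against a direct nearest
        hit/miss recomputation."""
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        kinds = {c: "continuous" for c in "abc"}
        got = relief_weights(X, y, kinds=kinds, k_neighbors=1)

        ranges = X.max() - X.min()
        diffs = {
            (i, j): (X.iloc[i] - X.iloc[j]).abs() / ranges
            for i in range(8) for j in range(8)
        }
        expected = pd.Series(0.0, index=X.columns)
        for i in range(8):
            dist = {j: diffs[(i, j)].mean() for j in range(8) if j != i}
            hits = [j for j in dist if y[j] == y[i]]
            misses = [j for j in dist if y[j] != y[i]]
            hit = min(hits, key=lambda j: (dist[j], j))
            miss = min(misses, key=lambda j: (dist[j], j))
            expected += diffs[(i, miss)] - diffs[(i, hit)]
        expected /= 8
        pd.testing.assert_series_equal(got, expected, check_names=False, atol=1e-12)

    def test_small_class_errors(self):
        X = pd.DataFrame({"f": np.arange(5.0)})
        with pytest.raises(ValueError, match="smaller"):
            relief_weights(X, [1, 0, 0, 0, 0], k_neighbors=3)


class TestDiscretize:
    def test_median_split(self):
        ages = np.arange(30.0, 50.0)
        codes, edges = discretize(ages, n_bins=2)
        assert (codes == (ages > np.median(ages)).astype(int)).all() or (
            np.bincount(codes).tolist() == [10, 10]
        )

    def test_constant_single_bin(self):
        codes, _ = discretize(np.full(7, 3.3), n_bins=3)
        assert (codes == 0).all()

    def test_uniform_quartiles_balanced(self):
        rng = np.random.default_rng(21)
        v = rng.uniform(size=100)
        codes, _ = discretize(v, n_bins=4)
        counts = np.bincount(codes, minlength=4)
        assert (np.abs(counts - 25) <= 1).all()

    def test_edges_reusable_on_new_data(self):
        train = np.arange(0.0, 10.0)
        _, edges = discretize(train, n_bins=2)
        codes, _ = discretize(np.array([-5.0, 100.0]), edges=edges)
        assert codes.tolist() == [0, 1]


class TestDispatcherProperties:
    @pytest.mark.parametrize("ranker", ["wmw", "wmw_uncor", "bwr"])
    def test_expression_rankers_cover_all_features(self, ranker):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(24, 6)), columns=list("abcdef"))
        y = np.array([0, 1] * 12)
        ranked = rank_features(ranker, X, y)
        assert set(ranked.feature_ids) <= set("abcdef")
        if ranker != "wmw_uncor":
            assert sorted(ranked.feature_ids) == list("abcdef")

    @pytest.mark.parametrize("ranker", ["infogain", "cfs", "relief"])
    def test_clinical_rankers_permutation_equivariant(self, ranker):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {
                "bin": rng.integers(0, 2, 30).astype(float),
                "ord": rng.integers(1, 4, 30).astype(float),
                "age": rng.normal(50, 10, 30),
            }
        )
        kinds = {"bin": "binary", "ord": "ordinal", "age": "continuous"}
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 1, 0
        perm = rng.permutation(30)
        r1 = rank_features(ranker, X, y, kinds)
        r2 = rank_features(
            ranker, X.iloc[perm].reset_index(drop=True), y[perm], kinds
        )
        assert r1.feature_ids == r2.feature_ids
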