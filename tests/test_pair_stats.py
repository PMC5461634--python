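import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lncrindiv.pair_stats import (
    bh_adjust,
    binomial_stability_pvalue,
    find_reversal_pairs,
    find_stable_pairs,
    fisher_reversal_pvalue,
    rank_transform,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_stable_pairs(values: pd.DataFrame, frac=0.95):
    """Exhaustive double loop over all ordered pairs."""
    out = []
    ids = list(values.index)
    for i, j in itertools.combinations(range(len(ids)), 2):
        xi, xj = values.iloc[i], values.iloc[j]
        a_ij = int((xi < xj).sum())
        a_ji = int((xj < xi).sum())
        for lo, hi, a, b in ((i, j, a_ij, a_ji), (j, i, a_ji, a_ij)):
            n = a + b
            if n > 0 and a / n > frac:
                out.append((ids[lo], ids[hi], a, b))
    return sorted(out)


def fisher_one_sided_enumeration(a, b, c, d):
    """Sum hypergeometric probabilities of all same-margin tables with >= d."""
    n1, n2, k = a + b, c + d, b + d
    total = 0.0
    for dd in range(max(0, k - n1), min(k, n2) + 1):
        if dd < d:
            continue
        total += (
            math.comb(n2, dd) * math.comb(n1, k - dd) / math.comb(n1 + n2, k)
        )
    return total


def bh_naive(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        q[idx] = prev = min(prev, p[idx] * m / rank)
    return q


# ---------------------------------------------------------------------------
# rank transform
# ---------------------------------------------------------------------------


class TestRankTransform:
    def test_simple_column(self):
        vals = pd.DataFrame({"s": [2.0, 5.0, 3.0]}, index=list("abc"))
        assert list(rank_transform(vals)["s"]) == [1, 3, 2]

    def test_average_tie_convention(self):
        vals = pd.DataFrame({"s": [1.0, 1.0, 2.0]}, index=list("abc"))
        assert list(rank_transform(vals)["s"]) == [1.5, 1.5, 3]

    def test_rank_sums(self, rng):
        vals = pd.DataFrame(rng.normal(size=(7, 5)))
        ranks = rank_transform(vals)
        assert np.allclose(ranks.sum(axis=0), 7 * 8 / 2)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        vals = pd.DataFrame(r.normal(size=(6, 4)))
        transformed = np.exp(0.3 * vals) + 5  # strictly increasing
        pd.testing.assert_frame_equal(rank_transform(vals), rank_transform(transformed))


# ---------------------------------------------------------------------------
# stable pairs
# ---------------------------------------------------------------------------


class TestStablePairs:
    def _values(self, arr):
        return pd.DataFrame(
            arr, index=[f"l{i}" for i in range(len(arr))],
            columns=[f"s{j}" for j in range(len(arr[0]))],
        )

    def test_always_ordered_pair_is_stable(self):
        vals = self._values([np.zeros(100), np.ones(100)])
        sp = find_stable_pairs(vals)
        assert len(sp) == 1
        assert (sp.loc[0, "low"], sp.loc[0, "high"]) == ("l0", "l1")

    def test_95_of_100_is_not_stable(self):
        # support exactly 0.95 must fail the strict > threshold
        lo = np.zeros(100)
        hi = np.ones(100)
        hi[:5] = -1.0  # flipped in 5 samples
        sp = find_stable_pairs(self._values([lo, hi]))
        assert len(sp) == 0

    def test_96_of_100_is_stable(self):
        lo = np.zeros(100)
        hi = np.ones(100)
        hi[:4] = -1.0
        sp = find_stable_pairs(self._values([lo, hi]))
        assert len(sp) == 1
        assert sp.loc[0, "a"] == 96 and sp.loc[0, "b"] == 4

    def test_exact_ties_count_for_neither_orientation(self):
        lo = np.zeros(10)
        hi = np.ones(10)
        hi[0] = 0.0  # tie in one sample
        sp = find_stable_pairs(self._values([lo, hi]))
        assert sp.loc[0, "a"] == 9 and sp.loc[0, "b"] == 0

    def test_matches_exhaustive_oracle_on_random_matrix(self, rng):
        vals = pd.DataFrame(
            rng.normal(8, 1.0, size=(20, 50)),
            index=[f"l{i:02d}" for i in range(20)],
            columns=[f"s{j}" for j in range(50)],
        )
        sp = find_stable_pairs(vals)
        got = sorted(zip(sp["low"], sp["high"], sp["a"], sp["b"]))
        assert got == brute_force_stable_pairs(vals)

    def test_threshold_validation(self, tiny_matrix):
        values, _ = tiny_matrix
        with pytest.raises(ValueError):
            find_stable_pairs(values, stability_frac=0.4)


# ---------------------------------------------------------------------------
# binomial stability p-value
# ---------------------------------------------------------------------------


class TestBinomialStability:
    def test_all_success_tail(self):
        assert binomial_stability_pvalue(10, 10) == pytest.approx(2**-10)

    def test_full_tail(self):
        assert binomial_stability_pvalue(0, 10) == 1.0

    def test_matches_exact_summation(self):
        for k, n in [(8, 12), (50, 60), (95, 100)]:
            exact = sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
            assert binomial_stability_pvalue(k, n) == pytest.approx(exact, rel=1e-12)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_stability_pvalue(11, 10)


# ---------------------------------------------------------------------------
# Fisher reversal p-value
# ---------------------------------------------------------------------------


class TestFisherReversal:
    def test_fully_reversed_table(self):
        assert fisher_reversal_pvalue(10, 0, 0, 10) == pytest.approx(
            1 / math.comb(20, 10), rel=1e-9
        )

    def test_no_reversal_in_cancer(self):
        assert fisher_reversal_pvalue(10, 0, 10, 0) == 1.0

    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        assert fisher_reversal_pvalue(a, b, c, d) == pytest.approx(
            fisher_one_sided_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )

    def test_matches_scipy_one_sided(self):
        for a, b, c, d in [(50, 2, 30, 22), (7, 1, 2, 6), (100, 5, 90, 15)]:
            ref = stats.fisher_exact([[d, c], [b, a]], alternative="greater")[1]
            assert fisher_reversal_pvalue(a, b, c, d) == pytest.approx(ref, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_reversal_pvalue(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_naive_and_dominates_p(self, pvals):
        q = bh_adjust(pvals)
        assert np.allclose(q, bh_naive(pvals))
        assert (q >= np.asarray(pvals) - 1e-12).all()
        # monotone nondecreasing in sorted-p order
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# reversal pairs end to end
# ---------------------------------------------------------------------------


class TestReversalPairs:
    def test_constructed_flip_is_found(self):
        # lncA < lncB stable in all 30 normals, fully reversed in all 30
        # cancers; a third far-away lncRNA never flips.
        n = 30
        normal = pd.DataFrame(
            [np.zeros(n), np.ones(n), np.full(n, 10.0)],
            index=["lncA", "lncB", "lncFar"],
        )
        cancer = normal.copy()
        cancer.loc["lncA"] = 2.0  # above lncB everywhere, still below lncFar
        stable = find_stable_pairs(normal)
        rev = find_reversal_pairs(stable, normal, cancer)
        assert len(rev) == 1
        assert (rev.loc[0, "low"], rev.loc[0, "high"]) == ("lncA", "lncB")
        assert rev.loc[0, "d"] == n

    def test_cancer_equal_normal_gives_empty_set(self, rng):
        normal = pd.DataFrame(rng.normal(8, 1, size=(10, 20)))
        stable = find_stable_pairs(normal)
        rev = find_reversal_pairs(stable, normal, normal.copy())
        assert len(rev) == 0

    def test_matches_composition_of_primitives(self, rng):
        normal = pd.DataFrame(
            rng.normal(8, 0.8, size=(12, 25)), index=[f"l{i}" for i in range(12)]
        )
        cancer = pd.DataFrame(
            rng.normal(8, 0.8, size=(12, 25)), index=normal.index,
            columns=[f"c{j}" for j in range(25)],
        )
        stable = find_stable_pairs(normal)
        rev = find_reversal_pairs(stable, normal, cancer, fdr=0.5)
        # recompute via the scalar primitives
        ps = []
        for _, row in stable.iterrows():
            lo, hi = row["low"], row["high"]
            c = int((cancer.loc[lo] < cancer.loc[hi]).sum())
            d = int((cancer.loc[lo] > cancer.loc[hi]).sum())
            ps.append(fisher_reversal_pvalue(row["a"], row["b"], c, d))
        qs = bh_adjust(ps)
        expected = stable[np.asarray(qs) < 0.5].reset_index(drop=True)
        assert list(rev["low"]) == list(expected["low"])
        assert list(rev["high"]) == list(expected["high"])

    def test_reversal_count_bounded_by_stable_count(self, rng):
        normal = pd.DataFrame(rng.normal(8, 0.6, size=(15, 30)))
        cancer = pd.DataFrame(rng.normal(8, 0.6, size=(15, 30)))
        stable = find_stable_pairs(normal)
        rev = find_reversal_pairs(stable, normal, cancer)
        assert len(rev) <= len(stable)
        # reversed orientation enriched in cancer for every reported pair
        if len(rev):
            assert (
                rev["d"] / (rev["c"] + rev["d"]) > rev["b"] / (rev["a"] + rev["b"])
            ).all()

    def test_invariance_under_monotone_transform(self, rng):
        normal = pd.DataFrame(rng.normal(8, 0.8, size=(10, 40)))
        cancer = pd.DataFrame(rng.normal(8.4, 0.8, size=(10, 40)))
        f = lambda x: np.log1p(np.exp(x / 4))  # strictly increasing
        s1 = find_stable_pairs(normal)
        s2 = find_stable_pairs(f(normal))
        pd.testing.assert_frame_equal(s1, s2)
        r1 = find_reversal_pairs(s1, normal, cancer)
        r2 = find_reversal_pairs(s2, f(normal), f(cancer))
        pd.testing.assert_frame_equal(r1, r2)
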