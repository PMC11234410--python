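from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batchfree.pmd import (
    build_knn,
    classify_positive,
    js_divergence,
    permutation_test,
    pmd,
)


def mixed_circle(n=40):
    """Cells on a circle, batches alternating: with k_nn=4 every
    neighbourhood holds exactly 2 cells of each batch = global proportions."""
    theta = 2 * np.pi * np.arange(n) / n
    emb = np.column_stack([np.cos(theta), np.sin(theta)])
    batches = np.where(np.arange(n) % 2 == 0, "a", "b")
    types = np.repeat("T", n)
    return emb, types, batches


class TestKnn:
    def test_collinear_geometry(self):
        emb = np.array([[0.0], [1.0], [10.0]])
        nn = build_knn(emb, 1)
        np.testing.assert_array_equal(nn.ravel(), [1, 0, 1])

    def test_duplicate_points_tie_break_by_index(self):
        emb = np.array([[0.0], [0.0], [0.0], [5.0]])
        nn = build_knn(emb, 2)
        np.testing.assert_array_equal(nn[3], [0, 1])
        np.testing.assert_array_equal(nn[2], [0, 1])

    def test_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(50, 3))
        nn = build_knn(emb, 7)
        for p in range(50):
            d = np.linalg.norm(emb - emb[p], axis=1)
            d[p] = np.inf
            expected = np.argsort(d, kind="stable")[:7]
            np.testing.assert_array_equal(nn[p], expected)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_knn(np.zeros((5, 2)), 5)


class TestClassifyPositive:
    def setup_method(self):
        self.neighbors = np.array([[1, 2, 3, 4]] * 5)

    def test_all_same_type_positive(self):
        types = np.array(["T"] * 5)
        assert classify_positive(0, self.neighbors, types)

    def test_no_same_type_negative(self):
        types = np.array(["T", "B", "B", "B", "B"])
        assert not classify_positive(0, self.neighbors, types)

    def test_exact_half_is_negative(self):
        # strict majority: 2 of 4 same-type neighbours does not qualify
        types = np.array(["T", "T", "T", "B", "B"])
        assert not classify_positive(0, self.neighbors, types)
        types = np.array(["T", "T", "T", "T", "B"])
        assert classify_positive(0, self.neighbors, types)


class TestJSDivergence:
    def test_closed_forms(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0)
        assert js_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-12)
        # direct formula: JS((1,0),(.5,.5)) = 1 - 0.5*log2(3) + 0.5 = 0.311278
        expected = 0.5 * (np.log2(2 / 1.5)) + 0.5 * (
            0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25))
        assert js_divergence([1, 0], [0.5, 0.5]) == pytest.approx(expected)
        assert expected == pytest.approx(0.3113, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        f = np.array(a[:n]) / np.sum(a[:n])
        g = np.array(b[:n]) / np.sum(b[:n])
        d1, d2 = js_divergence(f, g), js_divergence(g, f)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert -1e-12 <= d1 <= 1 + 1e-12
        assert js_divergence(f, f) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            js_divergence([1, 0], [1, 0, 0])


class TestPMD:
    def test_perfectly_mixed_circle(self):
        emb, types, batches = mixed_circle()
        r = pmd(emb, types, batches, k_nn=4)
        assert r.positive_rate == 1.0
        assert r.median_divergence == pytest.approx(0.0, abs=1e-12)

    def test_batch_specific_pure_cluster_scores_zero(self):
        # a cell type present in only one batch: one-hot neighbourhood vs
        # one-hot global profile -> divergence 0, not penalized
        rng = np.random.default_rng(1)
        shared_a = rng.normal(0, 0.1, size=(30, 2))
        shared_b = rng.normal(0, 0.1, size=(30, 2))
        specific = rng.normal(50, 0.1, size=(30, 2))
        emb = np.vstack([shared_a, shared_b, specific])
        types = np.array(["S"] * 60 + ["X"] * 30)
        batches = np.array(["a"] * 30 + ["b"] * 30 + ["a"] * 30)
        r = pmd(emb, types, batches, k_nn=10)
        flags = r.positive_flags
        assert flags[60:].all()
        pos_idx = np.flatnonzero(flags)
        div_specific = r.merge_divergence[np.isin(pos_idx, np.arange(60, 90))]
        np.testing.assert_allclose(div_specific, 0.0, atol=1e-12)

    def test_fully_separated_batches_divergence_third(self):
        # two batches, one type, embedded far apart: every neighbourhood is
        # single-batch one-hot vs global (0.5, 0.5) -> JS = 0.3113
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(40, 2))
        b = rng.normal(100, 0.1, size=(40, 2))
        emb = np.vstack([a, b])
        types = np.repeat("T", 80)
        batches = np.array(["a"] * 40 + ["b"] * 40)
        r = pmd(emb, types, batches, k_nn=10)
        assert r.positive_rate == 1.0
        assert r.median_divergence == pytest.approx(js_divergence([1, 0], [0.5, 0.5]), abs=1e-9)

    def test_positive_rate_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(100, 2))
        types = rng.choice(["T", "B"], size=100)
        batches = rng.choice(["a", "b"], size=100)
        rates = [pmd(emb, types, batches, k_nn=10, majority_threshold=t).positive_rate
                 for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(r1 >= r2 for r1, r2 in zip(rates, rates[1:]))

    def test_batch_relabeling_invariance(self):
        emb, types, batches = mixed_circle()
        r1 = pmd(emb, types, batches, k_nn=4)
        swapped = np.where(batches == "a", "zz", "aa")  # swap + rename
        r2 = pmd(emb, types, swapped, k_nn=4)
        assert r1.positive_rate == r2.positive_rate
        np.testing.assert_allclose(r1.merge_divergence, r2.merge_divergence, atol=1e-12)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError, match="two batches"):
            pmd(np.zeros((10, 2)), np.repeat("T", 10), np.repeat("a", 10), k_nn=3)


class TestPermutationTest:
    def test_identical_groups_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        p = permutation_test(x, list(x), n_perm=999, rng=0)
        assert p > 0.9

    def test_exhaustive_matches_enumeration_oracle(self):
        x = [100.0, 101.0, 102.0]
        y = [0.0, 1.0, 2.0]
        p = permutation_test(x, y, sided="two", exhaustive=True)
        # oracle: enumerate all C(6,3)=20 splits directly
        pooled = np.array(x + y)
        obs = abs(np.mean(x) - np.mean(y))
        hits = 0
        for idx in combinations(range(6), 3):
            sel = np.zeros(6, dtype=bool)
            sel[list(idx)] = True
            hits += abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12
        assert p == pytest.approx(hits / 20)
        assert p == pytest.approx(2 / 20)  # only the split and its mirror

    def test_one_sided_options(self):
        x = [10.0, 11.0, 12.0]
        y = [0.0, 1.0, 2.0]
        p_larger = permutation_test(x, y, sided="larger", exhaustive=True)
        p_smaller = permutation_test(x, y, sided="smaller", exhaustive=True)
        assert p_larger == pytest.approx(1 / 20)
        assert p_smaller == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(0.5, 1, size=15)
        p1 = permutation_test(x, y, n_perm=499, rng=7)
        p2 = permutation_test(x, y, n_perm=499, rng=7)
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])
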