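"""Exact rank inference, effect size, map normalization, and FDR control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from plantsync import (
    DyadSynchronySummary,
    NormalizedWtcStack,
    average_wtc_map,
    bh_fdr,
    cliffs_delta,
    compare_groups,
    mann_whitney_u,
    mean_wtc,
    normalize_time,
    pixelwise_test,
    wtc,
)
from plantsync.stats import exact_p_greater

from _reference import brute_cliffs_delta, enumerate_mann_whitney, stepup_bh

finite_floats = st.floats(-100, 100, allow_nan=False)
small_group = st.lists(finite_floats, min_size=1, max_size=6)


class TestMeanWtc:
    def test_hand_computed_mean(self, rng):
        x = rng.standard_normal(128)
        res = wtc(x, x, 180.0)
        res.r2 = np.array([[0.2, 0.4], [0.6, 0.8]])
        res.coi_mask = np.array([[True, True], [False, False]])
        assert mean_wtc(res) == pytest.approx(0.5)
        assert mean_wtc(res, coi_policy="inside_coi") == pytest.approx(0.3)

    def test_self_coherence_near_one(self, rng):
        x = rng.standard_normal(200)
        assert mean_wtc(wtc(x, x, 180.0)) > 0.999

    def test_empty_coi_selection_rejected(self, rng):
        x = rng.standard_normal(128)
        res = wtc(x, x, 180.0)
        res.coi_mask = np.zeros_like(res.coi_mask)
        with pytest.raises(ValueError):
            mean_wtc(res, coi_policy="inside_coi")


class TestMannWhitney:
    def test_complete_separation_8v8(self):
        u, p, method = mann_whitney_u(np.arange(8) + 100, np.arange(8), "greater")
        assert u == 64 and method == "exact"
        assert p == pytest.approx(1 / 12870)

    def test_small_example_vs_enumeration(self):
        """a=[1,3], b=[2,4]: U=1; two-sided p from the full 6-labeling
        enumeration is 2/3 under the doubled-smaller-tail convention."""
        u, p, method = mann_whitney_u([1, 3], [2, 4], "two-sided")
        u_ref, p_ref = enumerate_mann_whitney(np.array([1.0, 3.0]), np.array([2.0, 4.0]), "two-sided")
        assert u == u_ref == 1
        assert p == pytest.approx(p_ref) == pytest.approx(2 / 3)

    def test_tie_symmetry(self):
        vals = [1.0, 2.0, 2.0, 5.0]
        u, _, _ = mann_whitney_u(vals, vals, "two-sided")
        assert u == len(vals) ** 2 / 2

    def test_matches_enumeration_oracle_randomized(self, rng):
        """Exact path equals brute-force enumeration over all labelings for
        tie-free samples with pooled size <= 12."""
        for _ in range(60):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 13 - m))
            pooled = rng.standard_normal(m + n)
            a, b = pooled[:m], pooled[m:]
            for alt in ("greater", "two-sided"):
                res = mann_whitney_u(a, b, alt)
                u_ref, p_ref = enumerate_mann_whitney(a, b, alt)
                assert res.method == "exact"
                assert res.u == u_ref
                assert res.p_value == pytest.approx(p_ref)

    def test_matches_scipy_exact(self, rng):
        for _ in range(25):
            a = rng.standard_normal(7)
            b = rng.standard_normal(6)
            res = mann_whitney_u(a, b, "greater")
            ref = sps.mannwhitneyu(a, b, alternative="greater", method="exact")
            assert res.u == ref.statistic
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_or_tied_samples_flagged_asymptotic(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        assert mann_whitney_u(a, b, "greater").method == "asymptotic"
        assert mann_whitney_u([1, 2, 2], [2, 3], "greater").method == "asymptotic"

    def test_asymptotic_close_to_scipy(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(25) + 0.5
        res = mann_whitney_u(a, b, "two-sided")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0], "greater")


class TestCliffsDelta:
    def test_full_dominance(self):
        assert cliffs_delta([10, 11], [1, 2]) == 1.0

    def test_tied_groups(self):
        assert cliffs_delta([1, 2], [1, 2]) == 0.0

    @given(a=small_group, b=small_group)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_brute_force(self, a, b):
        d = cliffs_delta(a, b)
        assert d == pytest.approx(-cliffs_delta(b, a))
        assert d == pytest.approx(brute_cliffs_delta(np.array(a), np.array(b)))
        assert -1.0 <= d <= 1.0

    def test_u_identity_for_tie_free_groups(self, rng):
        """delta = 2U/(mn) - 1 whenever the pooled values are tie-free."""
        for _ in range(50):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            u, _, _ = mann_whitney_u(a, b, "greater")
            assert cliffs_delta(a, b) == pytest.approx(2 * u / 64 - 1)


class TestCompareGroups:
    @staticmethod
    def summaries(values, kind, axis="x"):
        return [
            DyadSynchronySummary(dyad_id=f"{kind}{i}", kind=kind, axis=axis, mean_wtc=v)
            for i, v in enumerate(values)
        ]

    def test_complete_separation(self):
        real = self.summaries(np.linspace(0.9, 0.95, 8), "real")
        pseudo = self.summaries(np.linspace(0.1, 0.15, 8), "pseudo")
        res = compare_groups(real, pseudo, axis="x")
        assert res.cliffs_delta == 1.0
        assert res.p_value == pytest.approx(2 / 12870)
        assert res.u_statistic == 64 and res.method == "exact"

    def test_identical_groups(self):
        vals = np.linspace(0.2, 0.9, 8)
        res = compare_groups(
            self.summaries(vals, "real"), self.summaries(vals, "pseudo"), axis="x"
        )
        assert res.cliffs_delta == 0.0
        assert res.p_value == 1.0

    def test_axis_mismatch_rejected(self):
        real = self.summaries([0.5, 0.6], "real", axis="x")
        pseudo = self.summaries([0.1, 0.2], "pseudo", axis="z")
        with pytest.raises(ValueError):
            compare_groups(real, pseudo, axis="x")


class TestNormalizeTime:
    def test_identity_resampling(self, rng):
        m = rng.random((5, 100))
        np.testing.assert_allclose(normalize_time(m, 100), m, atol=1e-12)

    def test_constant_matrix(self):
        m = np.full((3, 7), 0.42)
        np.testing.assert_allclose(normalize_time(m, 50), np.full((3, 50), 0.42))

    def test_two_columns_to_three_bins(self):
        m = np.array([[0.2, 0.8]])
        np.testing.assert_allclose(normalize_time(m, 3), [[0.2, 0.5, 0.8]])

    @given(
        rows=st.integers(1, 4),
        cols=st.integers(2, 30),
        n_bins=st.integers(2, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_preserves_row_bounds(self, rows, cols, n_bins, seed):
        m = np.random.default_rng(seed).random((rows, cols))
        out = normalize_time(m, n_bins)
        assert out.shape == (rows, n_bins)
        for src, dst in zip(m, out):
            assert dst.min() >= src.min() - 1e-12
            assert dst.max() <= src.max() + 1e-12

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            normalize_time(np.ones((2, 5)), 1)


class TestAverageMap:
    @staticmethod
    def stack(matrices):
        arr = np.stack(matrices)
        return NormalizedWtcStack(
            matrices=arr, n_bins=arr.shape[2], freqs=np.arange(arr.shape[1]) + 1.0
        )

    def test_single_matrix(self, rng):
        m = rng.random((4, 10))
        np.testing.assert_array_equal(average_wtc_map(self.stack([m])), m)

    def test_complement_symmetry(self, rng):
        m = rng.random((4, 10))
        np.testing.assert_allclose(average_wtc_map(self.stack([m, 1 - m])), 0.5)

    def test_hand_computed(self):
        a = np.array([[0.0, 0.4], [0.2, 1.0]])
        b = np.array([[1.0, 0.0], [0.4, 0.6]])
        np.testing.assert_allclose(
            average_wtc_map(self.stack([a, b])), [[0.5, 0.2], [0.3, 0.8]]
        )


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 6), [0.2] * 6)

    def test_matches_handrolled_stepup(self, rng):
        p = rng.uniform(1e-6, 1, size=200)
        np.testing.assert_allclose(bh_fdr(p), stepup_bh(p), atol=1e-12)
        assert bh_fdr(p).min() >= p.min() - 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPixelwise:
    @staticmethod
    def stack(arr):
        return NormalizedWtcStack(
            matrices=arr, n_bins=arr.shape[2], freqs=np.arange(arr.shape[1]) + 1.0
        )

    def test_identical_stacks_nothing_significant(self, rng):
        arr = rng.random((8, 6, 20))
        res = pixelwise_test(self.stack(arr), self.stack(arr.copy()))
        assert res.sig_mask.sum() == 0

    def test_complete_separation_all_significant(self, rng):
        pseudo = rng.uniform(0.0, 0.4, size=(8, 6, 20))
        real = pseudo + 0.5
        res = pixelwise_test(self.stack(real), self.stack(pseudo))
        np.testing.assert_allclose(res.p_map, 1 / 12870)
        np.testing.assert_allclose(res.q_map, 1 / 12870)
        assert res.sig_mask.all()

    def test_exact_p_matches_null_distribution(self, rng):
        real = rng.random((6, 3, 5))
        pseudo = rng.random((5, 3, 5))
        res = pixelwise_test(self.stack(real), self.stack(pseudo))
        for i in range(3):
            for j in range(5):
                u, p, method = mann_whitney_u(real[:, i, j], pseudo[:, i, j], "greater")
                assert method == "exact"
                assert res.p_map[i, j] == pytest.approx(p)
                assert p == pytest.approx(exact_p_greater(u, 6, 5))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pixelwise_test(self.stack(rng.random((4, 6, 20))), self.stack(rng.random((4, 5, 20))))
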