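"""Empirical AUC, ROC curve construction, DeLong variance and the
multi-group equality test, checked against naive independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    brute_force_auc,
    jackknife_auc_variance,
    permutation_auc_difference_p,
)
from mskscreen.roc import (
    UndefinedAUCError,
    auc_empirical,
    compare_auc_groups,
    delong_variance,
    roc_points,
)


@st.composite
def score_instances(draw, max_n=200, min_per_class=1):
    n = draw(st.integers(min_value=2 * min_per_class, max_value=max_n))
    scores = draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
    n_cases = draw(st.integers(min_value=min_per_class, max_value=n - min_per_class))
    outcomes = [1] * n_cases + [0] * (n - n_cases)
    return np.array(scores, dtype=float), np.array(outcomes)


class TestAucEmpirical:
    def test_perfect_separation(self):
        assert auc_empirical([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc_empirical([3, 3, 3, 3], [1, 0, 1, 0]) == 0.5

    def test_pairwise_toy_example(self):
        # cases {3,5}, controls {2,5,1}: wins 3>2,3>1,5>2,5>1, tie 5=5
        # -> (4 + 0.5) / 6 = 0.75
        s = [3, 5, 2, 5, 1]
        y = [1, 1, 0, 0, 0]
        assert auc_empirical(s, y) == pytest.approx(0.75, abs=1e-15)
        assert brute_force_auc(s, y) == pytest.approx(0.75, abs=1e-15)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc_empirical([1, 2, 3], [1, 1, 1])

    @given(score_instances())
    def test_matches_brute_force_and_trapezoid(self, inst):
        s, y = inst
        fast = auc_empirical(s, y)
        assert fast == pytest.approx(brute_force_auc(s, y), abs=1e-12)
        assert roc_points(s, y).auc == pytest.approx(fast, abs=1e-12)

    @given(score_instances(max_n=60))
    def test_tie_symmetry(self, inst):
        s, y = inst
        assert auc_empirical(s, y) + auc_empirical(-s, y) == pytest.approx(1.0, abs=1e-12)

    @given(score_instances(max_n=60), st.floats(-50, 50, allow_nan=False))
    def test_translation_invariance(self, inst, shift):
        s, y = inst
        assert auc_empirical(s + shift, y) == pytest.approx(auc_empirical(s, y), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(25):
            n = int(rng.integers(10, 120))
            s = rng.integers(0, 9, n).astype(float)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert auc_empirical(s, y) == pytest.approx(
                sklearn_metrics.roc_auc_score(y, s), abs=1e-12
            )


class TestRocPoints:
    @given(score_instances(max_n=100))
    def test_curve_shape(self, inst):
        s, y = inst
        roc = roc_points(s, y)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_integer_scores_bound_operating_points(self, rng):
        s = rng.integers(0, 9, 500).astype(float)
        y = rng.integers(0, 2, 500)
        roc = roc_points(s, y)
        # at most one point per distinct threshold plus the two anchors
        assert len(roc.fpr) <= 9 + 2

    def test_ci_truncated_to_unit_interval(self):
        roc = roc_points([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        lo, hi = roc.ci()
        assert (lo, hi) == (1.0, 1.0)  # perfect separation, zero variance


class TestDelongVariance:
    def test_perfect_separation_gives_zero(self):
        assert delong_variance([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0]) == 0.0

    def test_toy_set_exact_value_near_jackknife(self):
        # cases {3,5}, controls {2,5,1}: structural-components variance is
        # 25/360; the delete-one jackknife gives 31/360 — the estimators
        # differ by O(1/m) factors at m=2 cases, hence the loose band here
        s, y = [3, 5, 2, 5, 1], [1, 1, 0, 0, 0]
        dl = delong_variance(s, y)
        assert dl == pytest.approx(25 / 360, abs=1e-15)
        assert dl == pytest.approx(jackknife_auc_variance(s, y), rel=0.25)

    def test_matches_jackknife_at_moderate_n(self, rng):
        for _ in range(10):
            n = int(rng.integers(60, 100))
            s = rng.integers(0, 9, n).astype(float)
            y = np.r_[np.ones(n // 3, dtype=int), np.zeros(n - n // 3, dtype=int)]
            dl = delong_variance(s, y)
            jk = jackknife_auc_variance(s, y)
            assert dl == pytest.approx(jk, rel=0.10)

    def test_frozen_cross_check_against_proc(self):
        # frozen instance whose AUC/variance were verified against the R
        # package pROC (roc(); var()): auc 0.5381944, var 0.006569515
        rng = np.random.default_rng(3)
        y = (rng.random(60) < 0.4).astype(int)
        s = np.clip(np.round(rng.standard_normal(60) * 2 + 3 + 1.5 * y), 0, 8)
        assert auc_empirical(s, y) == pytest.approx(0.5381944444, abs=1e-9)
        assert delong_variance(s, y) == pytest.approx(0.006569515134958976, rel=1e-9)

    def test_too_few_per_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            delong_variance([5, 1, 2], [1, 0, 0])

    @given(score_instances(max_n=60, min_per_class=2), st.floats(-9, 9, allow_nan=False))
    def test_variance_translation_invariant(self, inst, shift):
        s, y = inst
        assert delong_variance(s + shift, y) == pytest.approx(
            delong_variance(s, y), abs=1e-15
        )


class TestCompareAucGroups:
    def test_identical_groups_give_null_result(self):
        s = np.array([1, 3, 5, 7, 2, 4, 2, 6], dtype=float)
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        res = compare_auc_groups([(s, y), (s, y)])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_separated_vs_noise_is_significant(self, rng):
        # group A separates perfectly (AUC 1); group B is pure noise.  A
        # record-label permutation test on the same data agrees (oracle).
        n = 100
        y = np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)]
        strong = np.r_[rng.integers(6, 9, 30), rng.integers(0, 3, 70)].astype(float)
        noise = rng.integers(0, 9, n).astype(float)
        with pytest.warns(UserWarning):
            res = compare_auc_groups([(strong, y), (noise, y)])
        assert res.p_value < 0.001
        p_perm = permutation_auc_difference_p(strong, y, noise, y, 150, rng)
        assert p_perm < 0.01

    def test_two_group_test_tracks_permutation_oracle(self, rng):
        # small unpaired instances: the chi-square p should approximately
        # match a record-permutation p for the AUC difference
        for sep in (0.0, 2.0):
            y1 = np.r_[np.ones(15, dtype=int), np.zeros(45, dtype=int)]
            y2 = np.r_[np.ones(15, dtype=int), np.zeros(45, dtype=int)]
            s1 = np.round(rng.standard_normal(60) * 2 + sep * y1 + 4)
            s2 = np.round(rng.standard_normal(60) * 2 + 4)
            p_chi = compare_auc_groups([(s1, y1), (s2, y2)]).p_value
            p_perm = permutation_auc_difference_p(s1, y1, s2, y2, 300, rng)
            assert (p_chi < 0.05) == (p_perm < 0.05) or abs(p_chi - p_perm) < 0.15

    def test_group_failing_preconditions_is_named(self):
        good = (np.array([1.0, 5.0, 2.0, 6.0]), np.array([0, 1, 0, 1]))
        bad = (np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        with pytest.raises(UndefinedAUCError, match="neck"):
            compare_auc_groups([good, bad], labels=["back", "neck"])

    def test_zero_variance_group_pins_weighted_mean(self):
        perfect = (np.array([7.0, 8.0, 1.0, 2.0]), np.array([1, 1, 0, 0]))
        a = (np.array([1.0, 5.0, 2.0, 6.0, 3.0, 4.0]), np.array([0, 1, 0, 1, 1, 0]))
        b = (np.array([2.0, 5.0, 1.0, 7.0, 3.0, 4.0]), np.array([0, 1, 0, 1, 1, 0]))
        with pytest.warns(UserWarning, match="perfect separation"):
            res = compare_auc_groups([perfect, a, b], labels=["p", "a", "b"])
        assert res.excluded == ("p",)
        assert res.df == 2
        # the non-separating groups are measured against AUC = 1
        w = 1.0 / res.variances[1:]
        assert res.chi_square == pytest.approx(float(np.sum(w * (res.aucs[1:] - 1.0) ** 2)))

    @given(score_instances(max_n=80, min_per_class=3))
    @settings(max_examples=25)
    def test_statistic_translation_invariant(self, inst):
        s, y = inst
        s2, y2 = s[::-1].copy() + 1, y[::-1].copy()
        base = compare_auc_groups([(s, y), (s2 - 1, y2)])
        shifted = compare_auc_groups([(s + 10, y), (s2 + 9, y2)])
        assert shifted.chi_square == pytest.approx(base.chi_square, abs=1e-9)
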