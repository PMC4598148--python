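"""ROC engine: AUC conventions, cutoffs, weight lattice, combined predictor."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqrisk.roc import (
    LabeledScores,
    combined_score,
    hanley_mcneil_se,
    minmax_scale,
    optimal_cutoff,
    optimize_combination,
    roc_curve,
    unpaired_t_test,
    weight_grid,
)


def pairwise_auc(scores, labels):
    """Oracle: mean over all (positive, negative) pairs of
    [pos > neg] + 0.5 * [pos == neg]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# strategy: small instances with both classes and deliberate ties
# (scores drawn from a small integer range)
labeled_instances = st.integers(2, 30).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 6), min_size=n, max_size=n),
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda ls: any(ls) and not all(ls)
        ),
    )
)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve(LabeledScores([1, 2, 3, 4], [False, False, True, True]))
        assert roc.auc == pytest.approx(1.0)
        assert not roc.failed

    def test_all_scores_identical_gives_half(self):
        roc = roc_curve(LabeledScores([3.0] * 6, [True, False] * 3))
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(LabeledScores([1.0, 2.0], [True, True]))

    def test_curve_anchored_at_corners(self):
        rng = np.random.default_rng(2)
        roc = roc_curve(
            LabeledScores(rng.normal(size=30), rng.random(30) < 0.4)
        )
        fpr = 1.0 - roc.specificity
        assert fpr[0] == 1.0 and roc.sensitivity[0] == 1.0
        assert fpr[-1] == 0.0 and roc.sensitivity[-1] == 0.0
        assert np.all(np.diff(roc.sensitivity) <= 0)

    @settings(max_examples=200, derandomize=True)
    @given(labeled_instances)
    def test_trapezoid_equals_pairwise_oracle(self, instance):
        scores, labels = instance
        roc = roc_curve(LabeledScores(scores, labels))
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(labeled_instances)
    def test_negated_scores_complement_auc(self, instance):
        scores, labels = instance
        a = roc_curve(LabeledScores(scores, labels)).auc
        b = roc_curve(LabeledScores([-s for s in scores], labels)).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn_on_random_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 60)
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            ours = roc_curve(LabeledScores(scores, labels)).auc
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_hanley_mcneil_closed_form(self):
        # hand-computed: A=0.8, n1=10, n2=20 -> Q1=0.8/1.2, Q2=1.28/1.8
        q1, q2 = 0.8 / 1.2, 2 * 0.64 / 1.8
        var = (0.8 * 0.2 + 9 * (q1 - 0.64) + 19 * (q2 - 0.64)) / 200
        assert hanley_mcneil_se(0.8, 10, 20) == pytest.approx(np.sqrt(var))


class TestOptimalCutoff:
    def test_perfect_separation_picks_lowest_positive_score(self):
        roc = roc_curve(LabeledScores([1, 2, 5, 6], [False, False, True, True]))
        cut = optimal_cutoff(roc)
        assert cut.threshold == 5.0
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0

    def test_uninformative_scores_tie_to_lowest_threshold(self):
        roc = roc_curve(LabeledScores([2.0] * 4, [True, False, True, False]))
        cut = optimal_cutoff(roc)
        assert cut.youden_j == pytest.approx(0.0)
        assert cut.threshold == 2.0

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            cut = optimal_cutoff(roc_curve(LabeledScores(scores, labels)))
            best_j, best_t = -np.inf, None
            for t in np.unique(scores):
                sens = (scores[labels] >= t).mean()
                spec = (scores[~labels] < t).mean()
                if sens + spec - 1 > best_j + 1e-12:
                    best_j, best_t = sens + spec - 1, t
            assert cut.threshold == best_t
            assert cut.youden_j == pytest.approx(best_j)

    def test_operating_point_reproducible_by_reclassification(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        cut = optimal_cutoff(roc_curve(LabeledScores(scores, labels)))
        assert cut.sensitivity == pytest.approx(
            (scores[labels] >= cut.threshold).mean()
        )
        assert cut.specificity == pytest.approx(
            (scores[~labels] < cut.threshold).mean()
        )


class TestMinmaxScale:
    def test_fixed_points(self):
        np.testing.assert_allclose(minmax_scale([0, 5, 10]), [0, 5, 10])
        np.testing.assert_allclose(minmax_scale([2, 4]), [0, 10])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            minmax_scale([3.0, 3.0, 3.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30).filter(
            lambda v: max(v) > min(v)
        ),
        st.floats(0.01, 100),
        st.floats(-100, 100),
    )
    def test_affine_invariance_and_tight_bounds(self, values, a, b):
        base = minmax_scale(values)
        assert base.min() == 0.0 and base.max() == pytest.approx(10.0)
        shifted = minmax_scale([a * v + b for v in values])
        np.testing.assert_allclose(shifted, base, atol=1e-6)


class TestWeightGrid:
    def test_single_predictor(self):
        assert weight_grid(1) == [(1.0,)]

    def test_two_predictors_have_21_vectors(self):
        grid = weight_grid(2, 5)
        assert len(grid) == 21
        assert grid[0] == (1.0, 0.0) and grid[-1] == (0.0, 1.0)

    def test_three_predictors_match_stars_and_bars_oracle(self):
        grid = weight_grid(3, 5)
        oracle = {
            (i / 20, j / 20, (20 - i - j) / 20)
            for i, j in itertools.product(range(21), range(21))
            if i + j <= 20
        }
        assert len(grid) == len(oracle) == 231  # C(22, 2)
        assert set(grid) == oracle
        assert all(sum(w) == pytest.approx(1.0, abs=1e-12) for w in grid)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            weight_grid(2, 7)


class TestCombinedScore:
    def test_unit_weight_returns_first_predictor(self):
        table = np.array([[1.0, 9.0], [4.0, 2.0]])
        np.testing.assert_allclose(combined_score(table, (1.0, 0.0)), [1.0, 4.0])

    def test_identical_predictors_are_a_fixed_point(self):
        col = np.array([0.0, 3.0, 10.0])
        table = np.column_stack([col, col])
        np.testing.assert_allclose(combined_score(table, (0.35, 0.65)), col)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(10)
        table = rng.uniform(0, 10, (15, 3))
        w = np.array([0.2, 0.45, 0.35])
        oracle = [sum(row[j] * w[j] for j in range(3)) for row in table]
        np.testing.assert_allclose(combined_score(table, w), oracle, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            combined_score(np.ones((4, 3)), (0.5, 0.5))


class TestOptimizeCombination:
    def test_single_predictor_degenerates_to_its_own_roc(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=30)[:, None]
        labels = rng.random(30) < 0.5
        res = optimize_combination(scores, labels)
        assert res.best_weights == (1.0,)
        assert res.best_auc == pytest.approx(
            roc_curve(LabeledScores(scores[:, 0], labels)).auc
        )

    def test_best_auc_dominates_each_single_predictor(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = rng.integers(20, 60)
            table = rng.normal(size=(n, 3))
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            res = optimize_combination(table, labels)
            for j in range(3):
                single = roc_curve(LabeledScores(table[:, j], labels)).auc
                assert res.best_auc >= single - 1e-12

    def test_argmax_matches_exhaustive_recomputation(self):
        rng = np.random.default_rng(13)
        table = rng.normal(size=(25, 2))
        labels = rng.random(25) < 0.5
        res = optimize_combination(table, labels, step_pct=10)
        scaled = np.column_stack([minmax_scale(table[:, j]) for j in range(2)])
        oracle = {
            w: roc_curve(LabeledScores(combined_score(scaled, w), labels)).auc
            for w in weight_grid(2, 10)
        }
        assert res.best_auc == pytest.approx(max(oracle.values()), abs=1e-12)
        # tie rule: first maximum in descending-lexicographic weight order
        expected = next(
            w for w in weight_grid(2, 10)
            if oracle[w] == pytest.approx(max(oracle.values()), abs=1e-12)
        )
        assert res.best_weights == expected

    def test_grid_is_exhaustive(self):
        rng = np.random.default_rng(14)
        table = rng.normal(size=(12, 3))
        labels = np.array([True, False] * 6)
        res = optimize_combination(table, labels)
        assert [w for w, _ in res.grid] == weight_grid(3, 5)


class TestUnpairedTTest:
    def test_identical_groups(self):
        t, df, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 4

    def test_constant_equal_groups_yield_t_zero(self):
        t, df, p = unpaired_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_antisymmetric_in_group_order(self):
        a, b = [4.1, 5.2, 6.0], [2.0, 2.5, 3.1, 2.2]
        t1, df1, p1 = unpaired_t_test(a, b)
        t2, df2, p2 = unpaired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2) and df1 == df2

    def test_textbook_instance_matches_pooled_formula(self):
        a = np.array([5.0, 6.0, 7.0])
        b = np.array([3.0, 4.0])
        sp2 = ((2 * a.var(ddof=1)) + (1 * b.var(ddof=1))) / 3
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 2))
        t, df, p = unpaired_t_test(a, b)
        assert t == pytest.approx(expected_t)
        assert df == 3

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            unpaired_t_test([1.0], [1.0, 2.0])
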