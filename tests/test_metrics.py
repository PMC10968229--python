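import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from linkerbench import (
    MetricBundle,
    ScoredSample,
    auc,
    auprc,
    f1_max,
    low_auc_ratio,
    mcc_max,
    mean_bundle,
    metric_bundle,
    pr_curve,
    roc_curve,
)

from _oracles import ap_step_sum, auc_pair_counting, f1_enumeration, mcc_enumeration

SAMPLE = ScoredSample([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])


class TestFrozenExamples:
    """Hand-checkable cases, values confirmed by the brute-force oracles."""

    def test_auc_three_of_four_pairs(self):
        assert auc(roc_curve(SAMPLE)) == pytest.approx(0.75)
        assert auc_pair_counting(SAMPLE.scores, SAMPLE.labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        s = ScoredSample([0.9, 0.1], [1, 0])
        b = metric_bundle(s, 0.5)
        assert (b.auc, b.auprc, b.f1max, b.mccmax) == (1.0, 1.0, 1.0, 1.0)
        assert b.low_auc_ratio == pytest.approx(4.0)  # 2/f for a perfect predictor

    def test_all_ties_is_random_level(self):
        s = ScoredSample([0.5] * 6, [1, 0, 1, 0, 0, 1])
        curve = roc_curve(s)
        assert auc(curve) == pytest.approx(0.5)
        assert mcc_max(s)[1] == pytest.approx(0.0)
        # constant scores, positive fraction pi: AUPRC = pi, F1max = 2pi/(1+pi)
        assert auprc(pr_curve(s)) == pytest.approx(0.5)
        assert f1_max(s)[1] == pytest.approx(2 * 0.5 / 1.5)

    def test_auprc_step_sum(self):
        assert auprc(pr_curve(SAMPLE)) == pytest.approx(5 / 6)

    def test_f1max_at_lenient_threshold(self):
        thr, val = f1_max(SAMPLE)
        assert (thr, val) == pytest.approx((0.7, 0.8))

    def test_mccmax_tie_breaks_to_higher_threshold(self):
        thr, val = mcc_max(SAMPLE)
        assert val == pytest.approx(2 / np.sqrt(12))
        assert thr == pytest.approx(0.9)  # 0.7 achieves the same MCC; 0.9 wins

    def test_all_positive_labels_f1(self):
        s = ScoredSample([0.3, 0.9, 0.5], [1, 1, 1])
        thr, val = f1_max(s)
        assert val == pytest.approx(1.0)
        assert thr == pytest.approx(0.3)


class TestLowAucRatio:
    def test_diagonal_is_one_for_every_f(self):
        diag = roc_curve(ScoredSample([0.5, 0.5], [1, 0]))
        for f in (0.01, 0.1292, 0.5, 0.99):
            assert low_auc_ratio(diag, f) == pytest.approx(1.0)

    @pytest.mark.parametrize("f", [0.05, 0.1292, 0.5])
    def test_perfect_predictor_hits_upper_bound(self, f):
        perfect = roc_curve(ScoredSample([0.9, 0.1], [1, 0]))
        assert low_auc_ratio(perfect, f) == pytest.approx(2.0 / f)

    def test_f_outside_unit_interval_rejected(self):
        curve = roc_curve(SAMPLE)
        for f in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                low_auc_ratio(curve, f)

    def test_matches_dense_grid_integration(self):
        """Partial area agrees with numeric integration of the interpolated curve."""
        rng = np.random.default_rng(5)
        s = ScoredSample(rng.random(200), rng.integers(0, 2, 200))
        curve = roc_curve(s)
        for f in (0.05, 0.3, 0.77):
            grid = np.linspace(0, f, 20001)
            tpr = np.interp(grid, curve.fpr, curve.tpr)
            expected = np.trapezoid(tpr, grid) / (f * f / 2)
            assert low_auc_ratio(curve, f) == pytest.approx(expected, abs=1e-4)


class TestDegenerate:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(ScoredSample([0.1, 0.9], [1, 1]))
        with pytest.raises(ValueError):
            mcc_max(ScoredSample([0.1], [1]))

    def test_label_score_shape_mismatch(self):
        with pytest.raises(ValueError):
            ScoredSample([0.1, 0.2], [1])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            ScoredSample([0.1, 0.2], [1, 2])


scored_samples = st.integers(1, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ys: 0 < sum(ys) < len(ys)
        ),
    )
)


@given(scored_samples)
def test_auc_equals_pair_counting(case):
    """Trapezoidal tie-grouped AUC == exhaustive Mann-Whitney pair counting."""
    scores, labels = case
    s = ScoredSample(scores, labels)
    expected = auc_pair_counting(scores, labels)
    assert auc(roc_curve(s)) == pytest.approx(expected)
    assert roc_auc_score(labels, scores) == pytest.approx(expected)


@given(scored_samples)
def test_threshold_scans_equal_enumeration(case):
    scores, labels = case
    s = ScoredSample(scores, labels)
    assert f1_max(s)[1] == pytest.approx(f1_enumeration(scores, labels))
    assert mcc_max(s)[1] == pytest.approx(mcc_enumeration(scores, labels))


@given(scored_samples)
def test_auprc_equals_step_enumeration(case):
    scores, labels = case
    s = ScoredSample(scores, labels)
    expected = ap_step_sum(scores, labels)
    assert auprc(pr_curve(s)) == pytest.approx(expected)
    assert average_precision_score(labels, scores) == pytest.approx(expected)


@given(scored_samples, st.sampled_from([0.05, 0.1292, 0.5]))
def test_rank_metrics_invariant_under_monotone_transform(case, f):
    scores, labels = case
    a = metric_bundle(ScoredSample(scores, labels), f)
    transformed = [np.expm1(3.0 * v) for v in scores]  # strictly increasing
    b = metric_bundle(ScoredSample(transformed, labels), f)
    assert np.allclose(a.as_array(), b.as_array())


@given(scored_samples, st.sampled_from([0.1, 0.33, 0.8]))
def test_low_auc_ratio_bounded_by_perfect_predictor(case, f):
    scores, labels = case
    ratio = low_auc_ratio(roc_curve(ScoredSample(scores, labels)), f)
    assert 0.0 <= ratio <= 2.0 / f + 1e-9


@given(scored_samples)
def test_f1max_dominates_every_fixed_threshold(case):
    scores, labels = case
    s = ScoredSample(scores, labels)
    best = f1_max(s)[1]
    y = np.asarray(labels)
    for t in np.linspace(-0.1, 1.1, 40):
        pred = np.asarray(scores) >= t
        tp = np.sum(pred & (y == 1))
        f1 = 2 * tp / (2 * tp + np.sum(pred & (y == 0)) + np.sum(~pred & (y == 1))) if tp else 0.0
        assert best >= f1 - 1e-12


@given(scored_samples)
def test_mccmax_symmetric_under_label_swap_and_negation(case):
    scores, labels = case
    a = mcc_max(ScoredSample(scores, labels))[1]
    flipped = ScoredSample([-v for v in scores], [1 - y for y in labels])
    assert mcc_max(flipped)[1] == pytest.approx(a)


def test_mean_bundle_is_elementwise_mean():
    b1 = MetricBundle(0.6, 1.0, 0.3, 0.4, 0.2, 0.5)
    b2 = MetricBundle(0.8, 3.0, 0.5, 0.6, 0.4, 0.5)
    m = mean_bundle([b1, b2])
    assert m.as_array() == pytest.approx((b1.as_array() + b2.as_array()) / 2)
    assert m.f_positive_rate == 0.5
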