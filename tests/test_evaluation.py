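"""Metric arithmetic, kappa, paired t-test and complexity accounting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score, confusion_matrix as sk_confusion

import eegdensenet as ed
from eegdensenet.evaluation import (
    DegenerateTestError,
    UndefinedMetricError,
    cohens_kappa,
    conv_macs,
)


class TestConfusion:
    def test_perfect_agreement(self):
        labels = np.array([0] * 6 + [1] * 4)
        cm = ed.confusion(labels, labels)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (6, 0, 0, 4)

    def test_all_predicted_positive(self):
        labels = np.array([0, 0, 1, 1])
        preds = np.zeros(4, dtype=int)  # positive class is 0 (left)
        cm = ed.confusion(labels, preds)
        assert cm.fn == 0 and cm.tn == 0
        assert cm.tp == 2 and cm.fp == 2

    def test_matches_brute_force_loop_on_random_pairs(self, rng):
        """O(n) loop oracle over 1000 random prediction pairs."""
        labels = rng.integers(0, 2, size=1000)
        preds = rng.integers(0, 2, size=1000)
        cm = ed.confusion(labels, preds, positive=0)
        tp = fn = fp = tn = 0
        for l, p in zip(labels, preds):
            if l == 0 and p == 0:
                tp += 1
            elif l == 0 and p == 1:
                fn += 1
            elif l == 1 and p == 0:
                fp += 1
            else:
                tn += 1
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)
        # and against scikit-learn's tabulation
        ref = sk_confusion(labels, preds, labels=[0, 1])
        np.testing.assert_array_equal(cm.as_array(), ref)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            ed.confusion(np.array([0, 1]), np.array([0]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ed.confusion(np.array([0, 2]), np.array([0, 1]))


class TestMetrics:
    def test_published_left_hand_counts(self):
        """Worked example: counts 50/6/4/40 give accuracy 0.900,
        sensitivity 50/54, specificity 40/46 under the non-standard
        definitions."""
        cm = ed.ConfusionMatrix(tp=50, fn=6, fp=4, tn=40)
        rep = ed.metrics(cm, mode="paper")
        assert rep.accuracy == pytest.approx(0.900, abs=1e-12)
        assert rep.sensitivity == pytest.approx(50 / 54, abs=1e-12)
        assert rep.specificity == pytest.approx(40 / 46, abs=1e-12)

    def test_published_right_hand_counts(self):
        cm = ed.ConfusionMatrix(tp=53, fn=4, fp=3, tn=43)
        rep = ed.metrics(cm, mode="paper")
        assert cm.total == 103  # kept as printed
        assert rep.accuracy == pytest.approx(96 / 103, abs=1e-12)
        assert rep.sensitivity == pytest.approx(53 / 56, abs=1e-12)
        assert rep.specificity == pytest.approx(43 / 47, abs=1e-12)

    def test_modes_agree_when_fp_equals_fn(self):
        cm = ed.ConfusionMatrix(tp=30, fn=5, fp=5, tn=20)
        a = ed.metrics(cm, mode="paper")
        b = ed.metrics(cm, mode="standard")
        assert a.sensitivity == b.sensitivity
        assert a.specificity == b.specificity

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_metric_ranges_and_mode_label(self, tp, fn, fp, tn):
        cm = ed.ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
        for mode in ("paper", "standard"):
            try:
                rep = ed.metrics(cm, mode=mode)
            except UndefinedMetricError:
                continue
            assert 0.0 <= rep.accuracy <= 1.0
            assert 0.0 <= rep.sensitivity <= 1.0
            assert 0.0 <= rep.specificity <= 1.0
            assert -1.0 <= rep.kappa <= 1.0
            assert rep.definitions_mode == mode

    def test_accuracy_invariant_under_positive_swap(self, rng):
        labels = rng.integers(0, 2, 200)
        preds = rng.integers(0, 2, 200)
        rep0 = ed.metrics(ed.confusion(labels, preds, positive=0), "paper")
        rep1 = ed.metrics(ed.confusion(labels, preds, positive=1), "paper")
        assert rep0.accuracy == rep1.accuracy
        # paper-mode sensitivity and specificity swap roles
        assert rep0.sensitivity == pytest.approx(rep1.specificity)
        assert rep0.specificity == pytest.approx(rep1.sensitivity)

    def test_zero_denominator_raises(self):
        cm = ed.ConfusionMatrix(tp=0, fn=5, fp=0, tn=5)
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            ed.metrics(cm, mode="paper")

    def test_mse_from_probabilities(self):
        labels = np.array([0, 1])
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        rep = ed.metrics(
            ed.confusion(labels, labels), probabilities=probs, labels=labels
        )
        assert rep.mse == 0.0
        assert ed.brier_mse(labels, np.array([[0.5, 0.5], [0.5, 0.5]])) == (
            pytest.approx(0.5)
        )


class TestKappa:
    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(
            ed.ConfusionMatrix(tp=30, fn=0, fp=0, tn=20)
        ) == pytest.approx(1.0, abs=1e-12)

    def test_marginal_independence_is_zero(self):
        # rows proportional to column marginals: expected = observed
        cm = ed.ConfusionMatrix(tp=12, fn=28, fp=18, tn=42)
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40),
        fp=st.integers(0, 40), tn=st.integers(0, 40),
    )
    def test_matches_sklearn_on_random_matrices(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        labels = np.array([0] * (tp + fn) + [1] * (fp + tn))
        preds = np.array([0] * tp + [1] * fn + [0] * fp + [1] * tn)
        cm = ed.confusion(labels, preds, positive=0)
        ours = cohens_kappa(cm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate one-label draws
            ref = cohen_kappa_score(labels, preds)
        if np.isnan(ref):  # sklearn's degenerate single-category case
            return
        assert ours == pytest.approx(ref, abs=1e-12)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p = ed.paired_ttest(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_on_small_vector(self):
        """Differences [1,2,3,4]: t = 2.5 / (sd/sqrt(4)) ~= 3.873."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.zeros(4)
        t, p = ed.paired_ttest(a, b)
        sd = np.std(a, ddof=1)
        assert t == pytest.approx(2.5 / (sd / 2.0), rel=1e-9)
        assert t == pytest.approx(3.873, abs=1e-3)
        assert 0.0 < p < 0.05

    def test_antisymmetry(self, rng):
        a, b = rng.random(8), rng.random(8)
        ta, pa = ed.paired_ttest(a, b)
        tb, pb = ed.paired_ttest(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(DegenerateTestError):
            ed.paired_ttest(np.ones(4), np.zeros(4))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ed.paired_ttest(np.array([1.0]), np.array([2.0]))


class TestComplexity:
    def test_single_conv_closed_form(self):
        assert conv_macs(8, 64, 64, 360) == 8 * 64 * 64 * 360 == 11_796_480

    def test_temporal_layer_of_default_config(self):
        rep = ed.complexity(ed.ModelConfig())
        by_name = {c.name: c for c in rep.layers}
        assert by_name["temporal_conv"].macs == 11_796_480

    def test_parameter_census_matches_model(self):
        """Closed-form per-layer parameter counts equal the framework's
        own census of instantiated arrays."""
        for cfg in (
            ed.ModelConfig(),
            ed.ModelConfig(n_channels=16, n_samples=360),
            ed.ModelConfig(
                n_channels=8, n_samples=72, temporal_kernel=16,
                separable_kernel=4, n_temporal_filters=4,
                depth_multiplier=2, n_pointwise_filters=6,
            ),
        ):
            rep = ed.complexity(cfg)
            model = ed.build_model(cfg, seed=0)
            assert rep.total_params == model.n_parameters()

    def test_totals_are_sums(self):
        rep = ed.complexity(ed.ModelConfig())
        assert rep.total_macs == sum(c.macs for c in rep.layers)
        assert rep.total_params == sum(c.params for c in rep.layers)
        assert rep.total_macs_millions == rep.total_macs / 1e6

    def test_convention_documented(self):
        rep = ed.complexity(ed.ModelConfig())
        assert "multiply-accumulate" in rep.convention
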