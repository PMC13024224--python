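"""Classification metrics, PR curves, Grad-CAM, and dataset evaluation."""

import numpy as np
import pytest

from gaitssl.backbone3d import BackboneConfig, GaitBackbone
from gaitssl.evaluation import (
    ConfusionCounts,
    binary_decision,
    binary_metrics,
    confusion_matrix3,
    evaluate,
    grad_cam,
    macro_metrics,
    pr_curve,
)
from gaitssl.experiments import restrict_head_to_lower_half
from gaitssl.synthetic_gait import GaitSample


class TestBinaryDecision:
    @pytest.mark.parametrize("p,expected", [
        (0.51, 2), (0.5, 1), (0.0, 1), (1.0, 2), (0.499, 1)])
    def test_threshold_rule(self, p, expected):
        assert binary_decision(p) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            binary_decision(1.2)


class TestBinaryMetrics:
    def test_hand_example(self):
        r = binary_metrics(ConfusionCounts(TP=8, FP=2, FN=2, TN=8))
        assert r.precision == pytest.approx(0.8)
        assert r.recall == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.8)
        assert r.npv == pytest.approx(0.8)
        assert r.accuracy == pytest.approx(0.8)
        assert r.undefined == []

    def test_perfect_classifier(self):
        r = binary_metrics(ConfusionCounts(TP=5, FP=0, FN=0, TN=5))
        assert r.precision == 1.0 and r.recall == 1.0
        assert r.sensitivity == 1.0 and r.ppv == 1.0

    def test_zero_denominator_flagged_not_zero(self):
        with pytest.warns(RuntimeWarning, match="precision undefined"):
            r = binary_metrics(ConfusionCounts(TP=0, FP=0, FN=3, TN=7))
        assert np.isnan(r.precision)
        assert "precision" in r.undefined


def _independent_macro(M):
    """Hand computation of the macro metrics, independent of the package."""
    C = M.shape[0]
    ps, rs = [], []
    for i in range(C):
        col = M[:, i].sum()
        row = M[i, :].sum()
        ps.append(M[i, i] / col if col else np.nan)
        rs.append(M[i, i] / row if row else np.nan)
    P, R = np.mean(ps), np.mean(rs)
    F1 = 2 * P * R / (P + R) if (P + R) else 0.0
    return P, R, F1, np.trace(M) / M.sum()


class TestMacroMetrics:
    def test_diagonal_matrix_is_perfect(self):
        M = np.diag([10, 5, 8])
        p, r, f1, acc = macro_metrics(M)
        assert (p, r, f1, acc) == (1.0, 1.0, 1.0, 1.0)

    def test_collapsed_class_recall(self):
        M = np.array([[10, 0, 0], [0, 10, 0], [10, 0, 0]])
        with pytest.warns(RuntimeWarning):
            p, r, f1, acc = macro_metrics(M)
        assert r == pytest.approx(2 / 3)

    def test_harmonic_fixed_point(self):
        # symmetric confusion: macro P = macro R, so macro F1 equals both
        M = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])
        p, r, f1, _ = macro_metrics(M)
        assert p == pytest.approx(r)
        assert f1 == pytest.approx(p)

    def test_harmonic_form_not_mean_of_per_class_f1(self):
        # a matrix where the harmonic of macro averages differs from the
        # mean of per-class F1 scores; the former is the contract
        M = np.array([[50, 0], [30, 20]])
        p, r, f1, _ = macro_metrics(M)
        f1_classes = []
        for i in range(2):
            pi = M[i, i] / M[:, i].sum()
            ri = M[i, i] / M[i, :].sum()
            f1_classes.append(2 * pi * ri / (pi + ri))
        mean_f1 = np.mean(f1_classes)
        assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)
        assert abs(f1 - mean_f1) > 0.01

    def test_oracle_agreement_20_random_matrices(self, rng):
        for _ in range(20):
            C = int(rng.integers(2, 5))
            M = rng.integers(1, 30, size=(C, C)).astype(float)
            got = macro_metrics(M)
            want = _independent_macro(M)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            macro_metrics(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            macro_metrics(np.zeros((1, 1)))


class TestPRCurve:
    def test_perfect_ranking(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        truth = [1, 1, 1, 0, 0]
        _, _, auc = pr_curve(scores, truth)
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        scores = [0.5] * 10
        truth = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        _, _, auc = pr_curve(scores, truth)
        assert auc == pytest.approx(0.3)

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        for _ in range(10):
            n = int(rng.integers(6, 30))
            scores = rng.random(n)
            truth = rng.integers(0, 2, size=n)
            if truth.sum() in (0, n):
                continue
            _, _, auc = pr_curve(scores, truth)
            assert auc == pytest.approx(
                average_precision_score(truth, scores), abs=1e-10)

    def test_brute_force_oracle_with_inversion(self):
        scores = np.array([0.9, 0.8, 0.55, 0.6, 0.3, 0.1])
        truth = np.array([1, 1, 1, 0, 0, 0])  # one inversion at 0.55/0.6
        _, _, auc = pr_curve(scores, truth)
        # enumerate every threshold by hand
        order = np.argsort(-scores)
        t = truth[order]
        tp = np.cumsum(t)
        fp = np.cumsum(1 - t)
        prec = tp / (tp + fp)
        rec = tp / truth.sum()
        expected = np.sum(np.diff(np.r_[0.0, rec]) * prec)
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.random(20)
        truth = rng.integers(0, 2, size=20)
        truth[0], truth[1] = 0, 1
        _, _, a = pr_curve(scores, truth)
        _, _, b = pr_curve(np.exp(3 * scores) + 7, truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            pr_curve([0.1, 0.9], [1, 1])


@pytest.fixture(scope="module")
def tiny_model():
    return GaitBackbone(BackboneConfig.make_tiny(), seed=0)


class TestGradCam:
    def test_normalization_contract(self, tiny_model, rng):
        clip = rng.random((1, 1, 8, 32, 32)).astype(np.float32)
        sal = grad_cam(clip, 0, tiny_model)
        assert sal.values.shape == (8, 32, 32)
        assert sal.values.min() >= 0.0 and sal.values.max() <= 1.0
        if not sal.degenerate:
            assert sal.values.max() == pytest.approx(1.0)

    def test_deterministic(self, tiny_model, rng):
        clip = rng.random((1, 1, 8, 32, 32)).astype(np.float32)
        a = grad_cam(clip, 1, tiny_model)
        b = grad_cam(clip, 1, tiny_model)
        assert np.array_equal(a.values, b.values)

    def test_lower_half_model_localizes_lower(self):
        # fixture model whose logits depend only on lower-half bins;
        # the input carries structure only in the lower half
        net = GaitBackbone(BackboneConfig.make_tiny(), seed=0)
        restrict_head_to_lower_half(net)
        rng = np.random.default_rng(0)
        clip = np.zeros((1, 1, 8, 32, 32), np.float32)
        clip[..., 16:, :] = rng.random((1, 1, 8, 16, 32))
        sal = grad_cam(clip, 0, net)
        assert not sal.degenerate
        assert sal.values[:, 16:].mean() > sal.values[:, :16].mean()


class _OracleModel:
    """Fake model that knows the truth (for evaluate() contracts)."""

    def __init__(self, lookup, n_classes=3):
        self.lookup = lookup
        self.calls = []

    def eval(self):
        pass

    def forward(self, X):
        out = np.full((len(X), 3), -10.0, dtype=np.float32)
        for i in range(len(X)):
            out[i, self.lookup[round(float(X[i].sum()), 3)]] = 10.0
        return out


def _make_samples(labels3, T=2):
    samples = []
    for i, l3 in enumerate(labels3):
        clip = np.full((1, 1, T, 8, 8), (i + 1) * 1e-4, dtype=np.float32)
        samples.append(GaitSample(clip=clip, subject_id=f"s{i}", label3=l3))
    return samples


class TestEvaluate:
    def test_oracle_model_scores_perfectly(self):
        labels = [11, 21, 22, 11, 21, 22]
        samples = _make_samples(labels)
        lookup = {round(float(s.clip.sum()), 3): (11, 21, 22).index(s.label3)
                  for s in samples}
        res = evaluate(_OracleModel(lookup), samples)
        assert res["accuracy3"] == 1.0
        r = res["report"]
        assert r.macro_p == r.macro_r == r.macro_f1 == 1.0
        assert r.pr_auc == pytest.approx(1.0)

    def test_majority_model_on_balanced_data(self):
        labels = [11, 21, 22] * 4
        samples = _make_samples(labels)
        lookup = {round(float(s.clip.sum()), 3): 0 for s in samples}
        with pytest.warns(RuntimeWarning):
            res = evaluate(_OracleModel(lookup), samples)
        assert res["accuracy3"] == pytest.approx(1 / 3)
        assert res["report"].macro_r == pytest.approx(1 / 3)

    def test_leakage_guard(self):
        samples = _make_samples([11, 21, 22])
        lookup = {round(float(s.clip.sum()), 3): 0 for s in samples}
        with pytest.raises(ValueError, match="leakage"):
            evaluate(_OracleModel(lookup), samples, train_subjects={"s0"})

    def test_binary_consistency_with_merged_predictions(self):
        # scoring the merged 3-class predictions must equal scoring the
        # binary decisions directly
        labels = [11, 11, 21, 22, 21, 11]
        samples = _make_samples(labels)
        pred_classes = [0, 1, 1, 2, 0, 0]
        lookup = {round(float(s.clip.sum()), 3): c
                  for s, c in zip(samples, pred_classes)}
        res = evaluate(_OracleModel(lookup), samples, task="binary")
        pred2 = [1 if c == 0 else 2 for c in pred_classes]
        true2 = [1 if l == 11 else 2 for l in labels]
        acc2 = np.mean([p == t for p, t in zip(pred2, true2)])
        assert res["accuracy2"] == pytest.approx(acc2)
        c = res["confusion2"]
        assert c.TP == sum(1 for p, t in zip(pred2, true2) if p == t == 2)

    def test_unlabeled_samples_rejected(self):
        s = GaitSample(clip=np.zeros((1, 1, 2, 8, 8)), subject_id="x")
        with pytest.raises(ValueError, match="no labeled"):
            evaluate(_OracleModel({}), [s])

    def test_confusion_matrix_totals(self):
        M = confusion_matrix3([11, 21, 22, 11], [11, 22, 22, 21])
        assert M.sum() == 4
        assert M[0, 0] == 1 and M[1, 2] == 1 and M[2, 2] == 1 and M[0, 1] == 1
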