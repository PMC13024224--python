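"""Losses, schedules, EMA tracking, pseudo-label gating, and the
training-loop degeneracies of the Mean Teacher engine."""

import math

import numpy as np
import pytest

from gaitssl.backbone3d import BackboneConfig
from gaitssl.mean_teacher import (
    MeanTeacherModel,
    TrainConfig,
    combined_loss,
    confidence_gate,
    consistency_loss,
    cross_entropy,
    ema_update,
    promote_pseudo_labels,
    ramp_lambda,
    softmax,
)
from gaitssl.synthetic_gait import GaitSample, generate_dataset
from gaitssl.video_data import AugmentConfig, subject_split


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax(np.zeros(3)), 1 / 3)

    def test_shift_invariance_and_ratio(self):
        p = softmax(np.array([5.0, 5.0 + math.log(2)]))
        assert np.allclose(p, [1 / 3, 2 / 3])

    def test_large_logits_no_overflow(self):
        p = softmax(np.array([1000.0, 0.0]))
        assert np.all(np.isfinite(p))
        assert p[0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        p = softmax(rng.normal(size=(5, 7)) * 50)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestCrossEntropy:
    def test_perfect_prediction(self):
        assert cross_entropy([1.0, 0.0, 0.0], [1, 0, 0]) == pytest.approx(0.0)

    @pytest.mark.parametrize("C", [2, 3, 5])
    def test_uniform_gives_log_C(self, C):
        p = np.full(C, 1 / C)
        Y = np.eye(C)[0]
        assert cross_entropy(p, Y) == pytest.approx(math.log(C), abs=1e-10)

    def test_hand_value(self):
        got = cross_entropy([0.7, 0.2, 0.1], [0, 1, 0])
        assert got == pytest.approx(-math.log(0.2), abs=1e-10)

    def test_malformed_label_raises(self):
        with pytest.raises(ValueError, match="one-hot"):
            cross_entropy([0.5, 0.5], [1, 1])
        with pytest.raises(ValueError, match="one-hot"):
            cross_entropy([0.5, 0.5], [0.5, 0.5])


class TestConsistencyLoss:
    def test_identical_distributions(self):
        assert consistency_loss([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_maximal_two_class(self):
        assert consistency_loss([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_hand_value(self):
        got = consistency_loss([0.6, 0.4], [0.5, 0.5])
        assert got == pytest.approx(0.02, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            consistency_loss([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_batch_average(self):
        ps = [[1.0, 0.0], [0.5, 0.5]]
        pt = [[0.0, 1.0], [0.5, 0.5]]
        assert consistency_loss(ps, pt) == pytest.approx(1.0)


class TestCombinedLoss:
    def test_lambda_zero_is_supervised_only(self):
        lb = combined_loss(0.8, 0.5, 0.0)
        assert lb.total == pytest.approx(0.8)

    def test_arithmetic_at_ceiling(self):
        lb = combined_loss(0.5, 0.2, 1.0)
        assert lb.total == pytest.approx(0.7)

    def test_empty_unlabeled_batch(self):
        lb = combined_loss(0.9, 0.0, 0.7)
        assert lb.total == pytest.approx(0.9)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            combined_loss(0.1, 0.1, -0.5)


class TestRampLambda:
    def test_endpoints_and_midpoint(self):
        assert ramp_lambda(0) == 0.0
        assert ramp_lambda(30) == 1.0
        assert ramp_lambda(15) == pytest.approx(0.5)

    def test_monotone_and_clamped(self):
        vals = [ramp_lambda(e) for e in range(101)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert max(vals) == 1.0

    def test_custom_ceiling(self):
        assert ramp_lambda(60, ramp_epochs=30, ceiling=0.5) == 0.5


class TestEmaUpdate:
    def test_single_step(self):
        tp = {"w": np.zeros(3)}
        th = {"w": np.ones(3)}
        ema_update(tp, th, 0.99)
        assert np.allclose(tp["w"], 0.01)

    def test_fixed_point(self):
        w = np.array([1.0, -2.0])
        tp, th = {"w": w.copy()}, {"w": w.copy()}
        ema_update(tp, th, 0.99)
        assert np.allclose(tp["w"], w)

    def test_closed_form_over_50_steps(self):
        alpha = 0.99
        theta0 = np.array([2.0])
        student = np.array([5.0])
        tp = {"w": theta0.copy()}
        for t in range(1, 51):
            ema_update(tp, {"w": student}, alpha)
            expected = alpha ** t * theta0 + (1 - alpha ** t) * student
            assert np.allclose(tp["w"], expected, atol=1e-10)

    def test_structure_mismatch_raises(self):
        with pytest.raises(ValueError):
            ema_update({"a": np.zeros(2)}, {"b": np.zeros(2)}, 0.99)
        with pytest.raises(ValueError, match="shape"):
            ema_update({"a": np.zeros(2)}, {"a": np.zeros(3)}, 0.99)


class TestConfidenceGate:
    def test_accept_above_threshold(self):
        recs = confidence_gate([[0.85, 0.10, 0.05]], tau=0.8)
        assert recs[0].accepted and recs[0].hard_label == 0

    def test_boundary_is_rejected(self):
        # strict inequality: confidence exactly tau does not pass
        recs = confidence_gate([[0.8, 0.1, 0.1]], tau=0.8)
        assert not recs[0].accepted

    def test_uniform_rejected(self):
        recs = confidence_gate([np.full(3, 1 / 3)], tau=0.4)
        assert not recs[0].accepted

    def test_soft_labels_sum_to_one(self, rng):
        p = softmax(rng.normal(size=(6, 3)))
        for rec in confidence_gate(p):
            assert rec.soft_label.sum() == pytest.approx(1.0, abs=1e-6)


def _dummy_samples(n, labeled=False, shape=(1, 1, 2, 8, 8)):
    out = []
    for i in range(n):
        clip = np.zeros(shape, dtype=np.float32)
        out.append(GaitSample(clip=clip, subject_id=f"u{i}",
                              label3=11 if labeled else None))
    return out


class TestPromotion:
    def test_mixed_pool_grows_by_accepted_count(self):
        pool = _dummy_samples(10)
        probs = np.full((10, 3), 1 / 3)
        for i in range(4):
            probs[i] = [0.9, 0.05, 0.05]
        recs = confidence_gate(probs, tau=0.8, samples=pool)
        labeled, remaining, n = promote_pseudo_labels(recs, [], pool)
        assert n == 4
        assert len(labeled) == 4 and len(remaining) == 6
        assert all(s.pseudo and s.label3 == 11 for s in labeled)

    def test_all_pass_empties_pool(self):
        pool = _dummy_samples(5)
        probs = np.tile([0.05, 0.9, 0.05], (5, 1))
        recs = confidence_gate(probs, tau=0.8, samples=pool)
        _, remaining, n = promote_pseudo_labels(recs, [], pool)
        assert remaining == [] and n == 5

    def test_none_pass_pool_unchanged(self):
        pool = _dummy_samples(5)
        probs = np.full((5, 3), 1 / 3)
        recs = confidence_gate(probs, tau=0.8, samples=pool)
        labeled, remaining, n = promote_pseudo_labels(recs, [], pool)
        assert n == 0 and len(remaining) == 5 and labeled == []

    def test_never_overwrites_ground_truth(self):
        pool = _dummy_samples(1, labeled=True)
        recs = confidence_gate([[0.9, 0.05, 0.05]], tau=0.8, samples=pool)
        with pytest.raises(ValueError, match="ground-truth"):
            promote_pseudo_labels(recs, [], pool)


@pytest.fixture(scope="module")
def small_dataset():
    samples = generate_dataset(12, (1 / 3, 1 / 3, 1 / 3), 1.0,
                               T=8, H=32, W=32, seed=77)
    split = subject_split([s.subject_id for s in samples], seed=77)
    return samples, split


def _tiny_cfg(**kw):
    base = dict(epochs=2, batch_size=4, lr=1e-3)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainingLoop:
    def test_empty_labeled_set_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            MeanTeacherModel([], [])

    def test_empty_unlabeled_equals_supervised(self, small_dataset):
        # with no unlabeled data the engine must degrade to plain
        # supervised training: identical loss trajectory for the same seed
        samples, split = small_dataset
        m1 = MeanTeacherModel.from_samples(samples, split, config=_tiny_cfg())
        m1.unlabeled = []
        m2 = MeanTeacherModel.from_samples(samples, split, config=_tiny_cfg())
        m2.unlabeled = []
        h1 = m1.fit(seed=3).history
        h2 = m2.fit(seed=3).history
        assert [e["sup_loss"] for e in h1] == [e["sup_loss"] for e in h2]

    def test_alpha_zero_teacher_equals_student(self, small_dataset):
        samples, split = small_dataset
        m = MeanTeacherModel.from_samples(
            samples, split, config=_tiny_cfg(alpha=0.0, epochs=1))
        res = m.fit(seed=1)
        sp = res.state.student_state()
        tp = res.state.teacher_state()
        for k in sp:
            assert np.allclose(sp[k], tp[k], atol=1e-7), k

    def test_teacher_follows_exact_ema(self, small_dataset):
        # the teacher is updated by the EMA recursion only - no gradients
        samples, split = small_dataset
        labeled = [s for s in samples
                   if split.mapping[s.subject_id] == "train"][:4]
        cfg = _tiny_cfg(epochs=1, batch_size=4, alpha=0.9)
        m = MeanTeacherModel(labeled, [], config=cfg)
        res = m.fit(seed=5)
        # reconstruct: theta'_T = a^T theta_0 + (1-a) sum a^(T-t) theta_t is
        # impractical without logging every step; with one batch per epoch,
        # exactly one step ran: theta' = a*theta_init + (1-a)*theta_1
        student = res.state.student_state()
        teacher = res.state.teacher_state()
        from gaitssl.backbone3d import GaitBackbone
        ss = np.random.SeedSequence(5)
        init_s = ss.spawn(4)[0]
        init_seed = int(init_s.generate_state(1)[0] % (2 ** 31 - 1))
        init_net = GaitBackbone(m.backbone_config, seed=init_seed)
        init_params = init_net.named_params()
        for k in init_params:
            expected = 0.9 * init_params[k] + 0.1 * student[k]
            assert np.allclose(teacher[k], expected, atol=1e-6), k

    def test_consistency_zero_for_identical_views_and_networks(self, rng):
        from gaitssl.backbone3d import GaitBackbone
        net = GaitBackbone(BackboneConfig.make_tiny(), seed=0)
        x = rng.random((2, 1, 8, 32, 32)).astype(np.float32)
        net.eval()
        p = softmax(net.forward(x))
        assert consistency_loss(p, p) == 0.0

    def test_history_and_summary(self, small_dataset):
        samples, split = small_dataset
        m = MeanTeacherModel.from_samples(samples, split, config=_tiny_cfg())
        res = m.fit(seed=0)
        assert len(res.history) == 2
        for key in ("lambda", "sup_loss", "val_loss", "val_acc", "lr"):
            assert key in res.history[0]
        text = res.summary()
        assert "EMA rate alpha" in text and "0.99" in text

    def test_reproducible_given_seed(self, small_dataset):
        samples, split = small_dataset
        runs = []
        for _ in range(2):
            m = MeanTeacherModel.from_samples(samples, split,
                                              config=_tiny_cfg(epochs=1))
            runs.append(m.fit(seed=9))
        a = runs[0].state.student_state()
        b = runs[1].state.student_state()
        for k in a:
            assert np.array_equal(a[k], b[k]), k

    def test_promotion_grows_supervising_pool(self, small_dataset):
        samples, split = small_dataset
        m = MeanTeacherModel.from_samples(samples, split, config=_tiny_cfg(
            epochs=3, ramp_epochs=1, tau=0.0))
        # tau=0: every teacher prediction passes the (strict) gate once
        # lambda > 0, so the whole pool promotes in the first phase-2 epoch
        m.unlabeled = _dummy_samples(3, shape=(1, 1, 8, 32, 32))
        res = m.fit(seed=2)
        promoted = sum(e["n_promoted"] for e in res.history)
        assert promoted == 3
        assert res.history[-1]["n_unlabeled"] == 0
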