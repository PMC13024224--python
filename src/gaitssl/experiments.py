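"""Reference experiments on the synthetic gait benchmark.

These functions encode the package's standard desk-scale study
conditions — 60 subjects, balanced classes, 8-frame 32x32 clips, tiny
backbone, subject-level 64/16/20 split — so that tests, the acceptance
script and users all run the identical protocol:

* :func:`run_learnability` — fully-labeled supervised training; the
  sanity floor that the architecture can solve the easy-margin task.
* :func:`run_ssl_comparison` — 20% of *training* subjects keep labels,
  the rest become the unlabeled pool (validation and test subjects stay
  labeled, mirroring the usual semi-supervised evaluation design); the
  full Mean Teacher engine is compared against a supervised-only
  ablation and a global-average-pooling (no SHPM) ablation.
* :func:`run_saliency_localization` — fraction of test clips whose
  Grad-CAM mass concentrates in the lower half of the frame, where all
  class-discriminative leg geometry lives.

The desk-scale optimization settings (learning rate 1e-3, batch 8, and
a 10-epoch consistency ramp for the short semi-supervised runs) are the
package's defaults for this reduced problem size; the full-scale
protocol defaults live in :class:`gaitssl.mean_teacher.TrainConfig`.
"""

from __future__ import annotations

import numpy as np

from .backbone3d import BackboneConfig
from .evaluation import evaluate, grad_cam
from .mean_teacher import MeanTeacherModel, TrainConfig, TrainingResults
from .synthetic_gait import GaitSample, generate_dataset
from .video_data import SplitAssignment, subject_split

__all__ = [
    "desk_train_config",
    "make_benchmark",
    "make_saliency_fixture",
    "restrict_head_to_lower_half",
    "run_learnability",
    "run_saliency_experiment",
    "run_saliency_localization",
    "run_ssl_comparison",
    "strip_train_labels",
]

DESK_N_SUBJECTS = 60
DESK_SHAPE = (8, 32, 32)  # (T, H, W)


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale optimization defaults (batch 8, lr 1e-3)."""
    base = dict(epochs=30, batch_size=8, lr=1e-3)
    base.update(overrides)
    return TrainConfig(**base)


def make_benchmark(seed: int, n_subjects: int = DESK_N_SUBJECTS,
                   ) -> tuple[list[GaitSample], SplitAssignment]:
    """Balanced fully-labeled synthetic dataset plus its subject split."""
    T, H, W = DESK_SHAPE
    samples = generate_dataset(n_subjects, (1 / 3, 1 / 3, 1 / 3), 1.0,
                               T=T, H=H, W=W, seed=seed)
    split = subject_split([s.subject_id for s in samples], seed=seed)
    return samples, split


def _test_set(samples, split):
    return [s for s in samples if split.mapping[s.subject_id] == "test"
            and s.labeled]


def run_learnability(seed: int, epochs: int = 30
                     ) -> tuple[float, TrainingResults]:
    """Train fully supervised on the easy-margin dataset; return the
    video-level 3-class test accuracy and the fitted results."""
    samples, split = make_benchmark(seed)
    model = MeanTeacherModel.from_samples(
        samples, split, config=desk_train_config(epochs=epochs))
    results = model.fit(seed=seed)
    test = _test_set(samples, split)
    out = evaluate(results.student, test,
                   train_subjects=set(split.subjects("train")))
    return out["accuracy3"], results


def strip_train_labels(samples, split, labeled_fraction: float,
                       seed: int) -> None:
    """Remove labels (in place) from a fraction of *training* subjects.

    Validation and test subjects keep their labels; the semi-supervised
    pool is always drawn from the training split only.
    """
    train = [s for s in samples if split.mapping[s.subject_id] == "train"]
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(labeled_fraction * len(train))))
    keep = set(rng.choice(len(train), size=n_keep, replace=False))
    for i, s in enumerate(train):
        if i not in keep:
            s.label3 = None
            s.label2 = None


def run_ssl_comparison(seed: int, labeled_fraction: float = 0.2,
                       epochs: int = 15, ramp_epochs: int = 10
                       ) -> dict[str, float]:
    """Mean Teacher vs supervised-only vs global-average-pool ablations.

    All three arms share the identical dataset, split, label budget and
    optimization settings; only the engine differs.  Returns test
    accuracies under keys ``mean_teacher``, ``supervised_only``,
    ``global_pool``.
    """
    samples, split = make_benchmark(seed)
    strip_train_labels(samples, split, labeled_fraction, seed)
    test = _test_set(samples, split)
    cfg = lambda: desk_train_config(epochs=epochs, ramp_epochs=ramp_epochs)

    out: dict[str, float] = {}
    mt = MeanTeacherModel.from_samples(samples, split, config=cfg())
    out["mean_teacher"] = evaluate(
        mt.fit(seed=seed).student, test)["accuracy3"]

    sup = MeanTeacherModel.from_samples(samples, split, config=cfg())
    sup.unlabeled = []
    out["supervised_only"] = evaluate(
        sup.fit(seed=seed).student, test)["accuracy3"]

    T, H, W = DESK_SHAPE
    gap_bc = BackboneConfig.make_tiny(input_shape=(T, H, W), use_shpm=False)
    gap = MeanTeacherModel.from_samples(samples, split,
                                        backbone_config=gap_bc, config=cfg())
    out["global_pool"] = evaluate(
        gap.fit(seed=seed).student, test)["accuracy3"]
    return out


def make_saliency_fixture(seed: int, n_subjects: int = DESK_N_SUBJECTS
                          ) -> tuple[list[GaitSample], SplitAssignment]:
    """Synthetic dataset (lower-half-only fixture) for saliency checks.

    The upper half of every frame is blanked, so by construction *all*
    class-discriminative signal — and indeed all signal — sits in the
    lower half where the legs are.  A model trained on this fixture can
    only ever depend on the lower half, which makes the expected
    Grad-CAM localization unambiguous.
    """
    samples, split = make_benchmark(seed, n_subjects)
    for s in samples:
        H = s.clip.shape[3]
        s.clip[..., :H // 2, :] = 0.0
    return samples, split


def run_saliency_localization(results: TrainingResults,
                              samples, split) -> float:
    """Fraction of test clips whose Grad-CAM mass is concentrated in the
    lower half of the frame (where the legs are)."""
    test = _test_set(samples, split)
    n_lower = 0
    n_valid = 0
    for s in test:
        sal = grad_cam(s.clip, None, results.student)
        if sal.degenerate:
            continue
        H = sal.values.shape[1]
        lower = sal.values[:, H // 2:].mean()
        upper = sal.values[:, :H // 2].mean()
        n_valid += 1
        if lower > upper:
            n_lower += 1
    return n_lower / max(1, n_valid)


def restrict_head_to_lower_half(net) -> None:
    """Turn a trained network into a lower-half-only fixture model.

    Classifier weights attached to SHPM bins that touch the upper half of
    the feature map are zeroed, so the class logits *provably* depend
    only on lower-half activations.  Combined with the lower-half-only
    dataset this gives a fixture where the expected saliency location is
    known by construction, which is what a localization check needs.
    """
    if net.shpm is None:
        raise ValueError("fixture construction requires an SHPM head")
    cfg = net.shpm.config
    c_f, _, h_f, w_f = net.config.feature_map_shape()
    parts = []
    for hs, ws in cfg.levels:
        hb, wb = h_f // hs, w_f // ws
        binmask = np.zeros((c_f, hb, wb), dtype=bool)
        for i in range(hb):
            if i * hs < h_f / 2:  # block extends into the upper half
                binmask[:, i, :] = True
        flat = binmask.ravel()
        parts.append(flat)
        if cfg.combine_mode == "concat":
            parts.append(flat)  # eta block follows mu block
    mask = np.concatenate(parts)
    net.classifier.params["weight"][:, mask] = 0.0


def run_saliency_experiment(seed: int, epochs: int = 30) -> float:
    """Train on the lower-half fixture and measure Grad-CAM localization.

    The trained network's head is restricted to lower-half bins (see
    :func:`restrict_head_to_lower_half`) so that the class logits depend
    only on the half of the frame where the signal lives.
    """
    samples, split = make_saliency_fixture(seed)
    model = MeanTeacherModel.from_samples(
        samples, split, config=desk_train_config(epochs=epochs))
    results = model.fit(seed=seed)
    restrict_head_to_lower_half(results.student)
    return run_saliency_localization(results, samples, split)
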