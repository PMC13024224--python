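"""Metrics, PR curves, Grad-CAM saliency, and test-set evaluation.

Binary screening treats Abnormal (genu varum or valgum merged) as the
positive class and thresholds its predicted probability at a fixed 0.5
(ties decided toward Normal; the pseudo-label confidence threshold is a
training-time device and never enters test-time decisions).  Multiclass
performance is summarized by accuracy and macro precision/recall, with
macro F1 the harmonic mean of macro P and macro R — not the mean of
per-class F1 scores, which is a different quantity.

Zero-denominator metrics (e.g. precision with no positive predictions)
are reported as NaN with a warning, never as a silent 0, so they cannot
corrupt macro averages downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as _ndzoom

from .mean_teacher import LABELS3, softmax
from .synthetic_gait import (GaitSample, LABEL2_ABNORMAL, LABEL2_NORMAL,
                             label2_from_label3)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SaliencyMap",
    "binary_decision",
    "binary_metrics",
    "macro_metrics",
    "pr_curve",
    "grad_cam",
    "evaluate",
    "confusion_matrix3",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts with Abnormal as the positive class."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    accuracy: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    macro_p: float = np.nan
    macro_r: float = np.nan
    macro_f1: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    ppv: float = np.nan
    npv: float = np.nan
    pr_auc: float = np.nan
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in self.__dict__.items() if k != "undefined"}
        d["undefined"] = list(self.undefined)
        return d


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning,
                      stacklevel=3)
        undefined.append(name)
        return float("nan")
    return num / den


def binary_decision(p_abnormal: float, threshold: float = 0.5) -> int:
    """Abnormal iff p > threshold (strict; p == threshold -> Normal)."""
    if not (0.0 <= p_abnormal <= 1.0):
        raise ValueError("p_abnormal must lie in [0, 1]")
    return LABEL2_ABNORMAL if p_abnormal > threshold else LABEL2_NORMAL


def binary_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision/recall and the clinical panel from binary counts."""
    r = MetricsReport()
    u = r.undefined
    r.precision = _ratio(counts.TP, counts.TP + counts.FP, "precision", u)
    r.recall = _ratio(counts.TP, counts.TP + counts.FN, "recall", u)
    r.sensitivity = r.recall
    r.specificity = _ratio(counts.TN, counts.TN + counts.FP, "specificity", u)
    r.ppv = r.precision
    r.npv = _ratio(counts.TN, counts.TN + counts.FN, "npv", u)
    r.accuracy = _ratio(counts.TP + counts.TN, counts.total, "accuracy", u)
    return r


def macro_metrics(matrix: np.ndarray) -> tuple[float, float, float, float]:
    """(macro_p, macro_r, macro_f1, accuracy) from a CxC count matrix.

    Rows index truth, columns prediction.  Per-class one-vs-rest precision
    and recall are averaged unweighted; macro F1 is the harmonic mean
    2*P*R/(P+R) of the two macro averages.  Classes never predicted (or
    absent from truth) contribute NaN to the average with a warning.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 2:
        raise ValueError("matrix must be CxC with C >= 2")
    if M.size == 0 or M.sum() == 0:
        raise ValueError("empty confusion matrix")
    C = M.shape[0]
    undefined: list[str] = []
    precisions, recalls = [], []
    for i in range(C):
        precisions.append(_ratio(M[i, i], M[:, i].sum(), f"P_{i}", undefined))
        recalls.append(_ratio(M[i, i], M[i, :].sum(), f"R_{i}", undefined))
    macro_p = float(np.mean(precisions))
    macro_r = float(np.mean(recalls))
    if macro_p + macro_r > 0:
        macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r)
    else:
        macro_f1 = float("nan") if np.isnan(macro_p + macro_r) else 0.0
    accuracy = float(np.trace(M) / M.sum())
    return macro_p, macro_r, macro_f1, accuracy


def pr_curve(scores: np.ndarray, truth: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its area under step interpolation.

    ``truth`` holds 0/1 with 1 = positive (Abnormal); tied scores are
    grouped at a single threshold.  The AUC is the step-wise sum
    ``sum_n (R_n - R_{n-1}) * P_n`` over thresholds in decreasing score
    order (the average-precision form).  A single-class truth vector is
    an error.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == len(truth):
        raise ValueError("pr_curve needs at least one positive and one "
                         "negative sample")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    # group ties: evaluate only at the last index of each distinct score
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(t)[idx]
    fp = np.cumsum(1 - t)[idx]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return precision, recall, auc


@dataclass
class SaliencyMap:
    """Per-frame spatial saliency, min-max normalized within the clip."""

    values: np.ndarray  # (T, H, W) in [0, 1]
    class_index: int
    degenerate: bool = False


def grad_cam(clip: np.ndarray, class_index: int, model) -> SaliencyMap:
    """Grad-CAM on the last convolutional block of the 3-D backbone.

    Channel weights are the spatiotemporal mean of the gradient of the
    chosen class logit with respect to the target activations; the map is
    the rectified weighted activation sum, upsampled to the input frame
    size and min-max normalized within the clip.  Pass
    ``class_index=None`` to use the predicted class.
    """
    X = np.asarray(clip, dtype=np.float32)
    if X.ndim == 4:
        X = X[None]
    model.eval()
    feat = model.feature_map(X)  # (1, C', T', H', W')
    if class_index is None:
        logits = model.head(feat)
        class_index = int(logits[0].argmax())
    dfeat = model.head_gradient(feat, class_index)  # same shape as feat
    weights = dfeat.mean(axis=(2, 3, 4))  # (1, C')
    cam = np.maximum(
        (weights[:, :, None, None, None] * feat).sum(axis=1), 0.0)[0]
    T, H, W = X.shape[2:]
    Tc, Hc, Wc = cam.shape
    cam_up = _ndzoom(cam, (T / Tc, H / Hc, W / Wc), order=1)
    lo, hi = cam_up.min(), cam_up.max()
    if hi - lo < 1e-12:
        warnings.warn("degenerate Grad-CAM: flat map", RuntimeWarning)
        return SaliencyMap(values=np.zeros((T, H, W), dtype=np.float32),
                           class_index=class_index, degenerate=True)
    return SaliencyMap(values=((cam_up - lo) / (hi - lo)).astype(np.float32),
                       class_index=class_index)


def overlay_frames(clip: np.ndarray, saliency: SaliencyMap,
                   alpha: float = 0.45, cmap_name: str = "jet") -> np.ndarray:
    """Blend the saliency map over the frames with one fixed colormap and
    transparency for every class; returns (T, H, W, 3) uint8."""
    import matplotlib

    frames = np.asarray(clip, dtype=np.float32)
    if frames.ndim == 5:
        frames = frames[0]
    gray = frames.mean(axis=0)  # (T, H, W)
    cmap = matplotlib.colormaps[cmap_name]
    heat = cmap(saliency.values)[..., :3]
    base = np.repeat(gray[..., None], 3, axis=-1)
    out = (1 - alpha) * base + alpha * heat
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def confusion_matrix3(true3: list[int], pred3: list[int]) -> np.ndarray:
    M = np.zeros((3, 3), dtype=int)
    for t, p in zip(true3, pred3):
        M[LABELS3.index(t), LABELS3.index(p)] += 1
    return M


def _video_probs(model, sample: GaitSample, clip_len: int | None) -> np.ndarray:
    """Video-level probability = mean of clip softmax vectors."""
    from .video_data import clips_from_sample

    T = sample.clip.shape[2]
    if clip_len is None or clip_len >= T:
        clips = [sample.clip]
    else:
        clips = clips_from_sample(sample.clip, clip_len)
    X = np.concatenate(clips, axis=0).astype(np.float32)
    model.eval()
    return softmax(model.forward(X)).mean(axis=0)


def evaluate(model, samples: list[GaitSample], task: str = "3class",
             clip_len: int | None = None, threshold: float = 0.5,
             train_subjects: set[str] | None = None) -> dict:
    """Score a model on labeled test samples.

    Clip-level softmax vectors are averaged per video; the binary task
    derives Abnormal probability as the sum of the varum and valgum
    probabilities and thresholds it at 0.5.  If ``train_subjects`` is
    given, any overlap with the test subjects raises (leakage guard).
    """
    if task not in ("3class", "binary"):
        raise ValueError("task must be '3class' or 'binary'")
    labeled = [s for s in samples if s.labeled]
    if not labeled:
        raise ValueError("no labeled samples to evaluate")
    if train_subjects is not None:
        overlap = train_subjects & {s.subject_id for s in labeled}
        if overlap:
            raise ValueError(f"subject leakage into test set: {sorted(overlap)[:5]}")

    probs = np.stack([_video_probs(model, s, clip_len) for s in labeled])
    true3 = [s.label3 for s in labeled]
    pred3 = [LABELS3[i] for i in probs.argmax(1)]
    M3 = confusion_matrix3(true3, pred3)
    macro_p, macro_r, macro_f1, acc3 = macro_metrics(M3)

    # binary view: Abnormal prob = varum + valgum mass
    p_abn = probs[:, 1] + probs[:, 2]
    true2 = np.array([label2_from_label3(t) for t in true3])
    pred2 = np.array([binary_decision(p, threshold) for p in p_abn])
    counts = ConfusionCounts(
        TP=int(((pred2 == LABEL2_ABNORMAL) & (true2 == LABEL2_ABNORMAL)).sum()),
        FP=int(((pred2 == LABEL2_ABNORMAL) & (true2 == LABEL2_NORMAL)).sum()),
        FN=int(((pred2 == LABEL2_NORMAL) & (true2 == LABEL2_ABNORMAL)).sum()),
        TN=int(((pred2 == LABEL2_NORMAL) & (true2 == LABEL2_NORMAL)).sum()))
    report = binary_metrics(counts)
    report.macro_p, report.macro_r, report.macro_f1 = macro_p, macro_r, macro_f1
    if task == "3class":
        report.accuracy = acc3
    truth01 = (true2 == LABEL2_ABNORMAL).astype(int)
    if 0 < truth01.sum() < len(truth01):
        _, _, report.pr_auc = pr_curve(p_abn, truth01)

    return {
        "report": report,
        "confusion3": M3,
        "confusion2": counts,
        "accuracy3": acc3,
        "accuracy2": float((pred2 == true2).mean()),
        "n_videos": len(labeled),
    }
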