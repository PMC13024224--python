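"""Synthetic frontal-view walking videos with controllable knee alignment.

The generator renders a simple articulated stick walker seen from the
front.  The clinically relevant degree of freedom is the frontal-plane
position of the knees relative to the straight hip-ankle line:

* knees displaced *outward* while the ankles stay approximated — genu
  varum ("bow-legged": the inter-condylar distance is positive at
  mid-stance);
* knees displaced *inward* while the ankles stay apart — genu valgum
  ("knock-kneed": the inter-malleolar distance is positive);
* knees on the hip-ankle line — normal alignment.

``knee_offset`` encodes this in fraction-of-leg-length units (negative =
outward/varum, positive = inward/valgum); the 3-class label is a
deterministic function of it with margin ``CLASS_MARGIN``.  Everything
else — walking speed (stride period), figure scale, pixel noise, gait
phase — is nuisance variation.

Label encodings follow the screening convention: 3-class 11 = Normal,
21 = Genu varum, 22 = Genu valgum; binary 1 = Normal, 2 = Abnormal
(varum and valgum merged).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import disk, line_aa

__all__ = [
    "WalkerParams",
    "GaitSample",
    "CLASS_MARGIN",
    "NUISANCE_RANGES",
    "LABEL3_NORMAL",
    "LABEL3_VARUM",
    "LABEL3_VALGUM",
    "LABEL2_NORMAL",
    "LABEL2_ABNORMAL",
    "label3_from_offset",
    "label2_from_label3",
    "pose_at_phase",
    "render_clip",
    "generate_dataset",
    "leg_region_mask",
    "geometric_classifier",
    "write_dataset",
    "read_manifest",
]

# label encodings
LABEL3_NORMAL, LABEL3_VARUM, LABEL3_VALGUM = 11, 21, 22
LABEL2_NORMAL, LABEL2_ABNORMAL = 1, 2

#: class-boundary margin on knee_offset (fraction of leg length)
CLASS_MARGIN = 0.05

#: per-subject nuisance parameter ranges (uniform draws)
NUISANCE_RANGES = {
    "stride_period": (8, 24),        # frames per gait cycle (integer)
    "height_frac": (0.5, 0.9),       # walker height as fraction of frame H
    "noise_sd": (0.0, 0.05),         # additive pixel noise
}

#: knee_offset sampling bands per class, in fraction-of-leg-length units.
#: The easy-margin bands keep a clear gap to the +-CLASS_MARGIN boundary.
OFFSET_BANDS = {
    LABEL3_NORMAL: (-0.02, 0.02),
    LABEL3_VARUM: (-0.30, -0.15),
    LABEL3_VALGUM: (0.15, 0.30),
}


@dataclass(frozen=True)
class WalkerParams:
    """Geometry and nuisance parameters of one synthetic walker.

    knee_offset : signed horizontal knee displacement off the hip-ankle
        line, in fraction-of-leg-length units (negative = outward/varum,
        positive = inward/valgum).
    stride_period : frames per full gait cycle (>= 4).
    walker_height : head-to-ground height in pixels.
    noise_sd : additive Gaussian pixel noise standard deviation.
    phase0 : initial gait phase in [0, 1).
    """

    knee_offset: float = 0.0
    stride_period: int = 12
    walker_height: float = 48.0
    noise_sd: float = 0.0
    phase0: float = 0.0

    def __post_init__(self):
        if self.stride_period < 4:
            raise ValueError("stride_period must be >= 4 frames")
        if not (0.0 <= self.phase0 < 1.0):
            raise ValueError("phase0 must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def label3(self) -> int:
        return label3_from_offset(self.knee_offset)


def label3_from_offset(knee_offset: float, margin: float = CLASS_MARGIN) -> int:
    """Deterministic 3-class label from the knee offset."""
    if knee_offset <= -margin:
        return LABEL3_VARUM
    if knee_offset >= margin:
        return LABEL3_VALGUM
    return LABEL3_NORMAL


def label2_from_label3(label3: int) -> int:
    """Binary merge rule: Abnormal includes both varum and valgum."""
    if label3 not in (LABEL3_NORMAL, LABEL3_VARUM, LABEL3_VALGUM):
        raise ValueError(f"unknown 3-class label {label3}")
    return LABEL2_NORMAL if label3 == LABEL3_NORMAL else LABEL2_ABNORMAL


@dataclass
class GaitSample:
    """One clip with subject identity and (optional) labels.

    ``clip`` is a (1, C, T, H, W) float array with values in [0, 1].
    ``pseudo`` marks samples whose label was assigned by a model rather
    than by ground truth.
    """

    clip: np.ndarray
    subject_id: str
    label3: int | None = None
    label2: int | None = None
    pseudo: bool = False

    def __post_init__(self):
        if self.clip.ndim != 5 or self.clip.shape[0] != 1:
            raise ValueError("clip must be (1, C, T, H, W)")
        if self.label3 is not None and self.label2 is None:
            self.label2 = label2_from_label3(self.label3)

    @property
    def labeled(self) -> bool:
        return self.label3 is not None


# ---------------------------------------------------------------------------
# pose model
# ---------------------------------------------------------------------------

def pose_at_phase(params: WalkerParams, phase: float,
                  frame_hw: tuple[int, int] | None = None,
                  center_x: float | None = None) -> dict[str, tuple[float, float]]:
    """Joint coordinates (x, y) in pixels at a given gait phase.

    Phase is taken modulo 1 after adding ``params.phase0`` so that
    ``pose_at_phase(p, phi)`` equals ``pose_at_phase(p shifted by phi, 0)``.
    At phase 0 the walker is at mid-stance (both feet planted); each leg's
    ankle lifts once per cycle, the two legs in antiphase.

    Proportions (fractions of walker height): head radius 0.07, hip line at
    0.50 from the top, leg length 0.50, hip half-width 0.11.  Knees are
    placed halfway down the leg and displaced horizontally by
    ``-side * knee_offset * leg_length`` (side = -1 for the left/-x leg),
    i.e. negative offsets push both knees outward (varum) and positive
    offsets pull them inward (valgum).
    """
    Hgt = params.walker_height
    phi = (params.phase0 + phase) % 1.0
    if frame_hw is not None:
        H, W = frame_hw
        cx = center_x if center_x is not None else W / 2.0
        top = (H - Hgt) / 2.0
    else:
        cx = center_x if center_x is not None else 0.0
        top = 0.0

    head_r = 0.07 * Hgt
    hip_y = top + 0.50 * Hgt
    leg_len = 0.50 * Hgt
    hip_half = 0.11 * Hgt
    ground_y = top + Hgt

    # vertical bob of the trunk, small and twice per cycle
    bob = 0.01 * Hgt * np.sin(4 * np.pi * phi)

    joints: dict[str, tuple[float, float]] = {}
    joints["head"] = (cx, top + head_r + bob)
    joints["neck"] = (cx, top + 2 * head_r + bob)
    joints["pelvis"] = (cx, hip_y + bob)

    lift_amp = 0.08 * Hgt
    for side_name, side in (("l", -1.0), ("r", +1.0)):
        hip_x = cx + side * hip_half
        ankle_x = hip_x  # ankles track the hips in the frontal plane
        # one lift per cycle per leg, legs in antiphase; phase 0 = both down
        leg_phi = phi + (0.25 if side < 0 else 0.75)
        lift = lift_amp * max(0.0, np.sin(2 * np.pi * leg_phi))
        ankle_y = ground_y - 0.05 * Hgt - lift
        knee_x = 0.5 * (hip_x + ankle_x) - side * params.knee_offset * leg_len
        knee_y = hip_y + bob + 0.5 * (ankle_y - hip_y - bob)
        joints[f"hip_{side_name}"] = (hip_x, hip_y + bob)
        joints[f"knee_{side_name}"] = (knee_x, knee_y)
        joints[f"ankle_{side_name}"] = (ankle_x, ankle_y)
        joints[f"foot_{side_name}"] = (ankle_x + side * 0.06 * Hgt, ankle_y)

    if frame_hw is not None:
        H, W = frame_hw
        for name, (x, y) in joints.items():
            if not (0 <= x < W and 0 <= y < H):
                raise ValueError(
                    f"walker joint {name} at ({x:.1f}, {y:.1f}) exceeds "
                    f"frame bounds {H}x{W}; reduce walker_height or offsets")
    return joints


_BONES = [
    ("head", "neck"), ("neck", "pelvis"),
    ("pelvis", "hip_l"), ("pelvis", "hip_r"),
    ("hip_l", "knee_l"), ("knee_l", "ankle_l"), ("ankle_l", "foot_l"),
    ("hip_r", "knee_r"), ("knee_r", "ankle_r"), ("ankle_r", "foot_r"),
]


def _draw_frame(joints: dict[str, tuple[float, float]], H: int, W: int,
                head_r: float) -> np.ndarray:
    img = np.zeros((H, W), dtype=np.float32)
    for a, b in _BONES:
        (xa, ya), (xb, yb) = joints[a], joints[b]
        rr, cc, val = line_aa(int(round(ya)), int(round(xa)),
                              int(round(yb)), int(round(xb)))
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        img[rr[keep], cc[keep]] = np.maximum(
            img[rr[keep], cc[keep]], val[keep].astype(np.float32))
    hx, hy = joints["head"]
    rr, cc = disk((hy, hx), max(1.5, head_r), shape=(H, W))
    img[rr, cc] = 1.0
    for j in ("knee_l", "knee_r", "ankle_l", "ankle_r"):
        jx, jy = joints[j]
        rr, cc = disk((jy, jx), 1.5, shape=(H, W))
        img[rr, cc] = 1.0
    return img


def render_clip(params: WalkerParams, T: int, H: int, W: int, seed: int = 0,
                subject_id: str = "s0", labeled: bool = True,
                channels: int = 1) -> GaitSample:
    """Render T grayscale frames of the walker; deterministic given seed.

    Set ``channels=3`` to tile the single gray channel into RGB.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    head_r = 0.07 * params.walker_height
    frames = np.empty((T, H, W), dtype=np.float32)
    for t in range(T):
        phase = t / params.stride_period
        joints = pose_at_phase(params, phase, frame_hw=(H, W))
        frames[t] = _draw_frame(joints, H, W, head_r)
    if params.noise_sd > 0:
        frames = frames + rng.normal(
            0.0, params.noise_sd, size=frames.shape).astype(np.float32)
    frames = np.clip(frames, 0.0, 1.0)
    clip = frames[None, None]  # (1, 1, T, H, W)
    if channels == 3:
        clip = np.repeat(clip, 3, axis=1)
    elif channels != 1:
        raise ValueError("channels must be 1 or 3")
    label3 = params.label3 if labeled else None
    return GaitSample(clip=clip, subject_id=subject_id, label3=label3)


def leg_region_mask(params: WalkerParams, H: int, W: int,
                    pad: int = 3) -> np.ndarray:
    """Boolean mask covering every pixel the legs can touch at any phase."""
    mask = np.zeros((H, W), dtype=bool)
    xs, ys = [], []
    for phi in np.linspace(0, 1, 32, endpoint=False):
        joints = pose_at_phase(params, phi, frame_hw=(H, W))
        for j in ("hip_l", "hip_r", "knee_l", "knee_r",
                  "ankle_l", "ankle_r", "foot_l", "foot_r"):
            x, y = joints[j]
            xs.append(x)
            ys.append(y)
    x0 = max(0, int(min(xs)) - pad)
    x1 = min(W, int(max(xs)) + pad + 1)
    y0 = max(0, int(min(ys)) - pad)
    y1 = min(H, int(max(ys)) + pad + 1)
    mask[y0:y1, x0:x1] = True
    return mask


def geometric_classifier(sample_params: WalkerParams) -> int:
    """Trivial alignment classifier from mid-stance geometry.

    Recomputes the anatomical criterion from the rendered pose: at stance
    (phase 0), compare inter-knee with inter-ankle horizontal distance.
    Knees wider than ankles beyond the class margin -> varum; narrower ->
    valgum; else normal.
    """
    joints = pose_at_phase(sample_params, 0.0)
    knee_gap = joints["knee_r"][0] - joints["knee_l"][0]
    ankle_gap = joints["ankle_r"][0] - joints["ankle_l"][0]
    leg_len = 0.50 * sample_params.walker_height
    # factor 2: both knees are displaced symmetrically
    rel = (knee_gap - ankle_gap) / (2.0 * leg_len)
    if rel >= CLASS_MARGIN:
        return LABEL3_VARUM
    if rel <= -CLASS_MARGIN:
        return LABEL3_VALGUM
    return LABEL3_NORMAL


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _class_counts(n: int, mix: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment (deterministic, ties to lower index)."""
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    raw = [n * p for p in mix]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_dataset(n_subjects: int,
                     class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                     labeled_fraction: float = 1.0,
                     T: int = 8, H: int = 32, W: int = 32,
                     seed: int = 0,
                     noise: bool = True,
                     return_params: bool = False):
    """One rendered clip per synthetic subject.

    ``class_mix`` orders classes (Normal, Varum, Valgum).  Per-subject
    nuisance parameters (stride period, figure scale, noise level, initial
    phase) are drawn uniformly from :data:`NUISANCE_RANGES`; ``noise=False``
    forces noise_sd to 0 for geometric ground-truth checks.  Labels are
    *removed* (set to None) for the unlabeled fraction, chosen at random.
    """
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must lie in [0, 1]")
    counts = _class_counts(n_subjects, tuple(class_mix))
    n_nonzero = sum(1 for p in class_mix if p > 0)
    if n_subjects < n_nonzero:
        raise ValueError(
            f"n_subjects={n_subjects} smaller than the {n_nonzero} classes "
            "with nonzero proportion")
    rng = np.random.default_rng(seed)
    classes = [LABEL3_NORMAL, LABEL3_VARUM, LABEL3_VALGUM]
    assignments = np.repeat(classes, counts)
    rng.shuffle(assignments)

    samples: list[GaitSample] = []
    all_params: list[WalkerParams] = []
    n_labeled = int(round(labeled_fraction * n_subjects))
    labeled_idx = set(rng.choice(n_subjects, size=n_labeled, replace=False))
    for i, cls in enumerate(assignments):
        lo, hi = OFFSET_BANDS[int(cls)]
        sp_lo, sp_hi = NUISANCE_RANGES["stride_period"]
        hf_lo, hf_hi = NUISANCE_RANGES["height_frac"]
        ns_lo, ns_hi = NUISANCE_RANGES["noise_sd"]
        params = WalkerParams(
            knee_offset=float(rng.uniform(lo, hi)),
            stride_period=int(rng.integers(sp_lo, sp_hi + 1)),
            walker_height=float(rng.uniform(hf_lo, hf_hi)) * H,
            noise_sd=float(rng.uniform(ns_lo, ns_hi)) if noise else 0.0,
            phase0=float(rng.uniform(0.0, 1.0)),
        )
        clip_seed = int(rng.integers(0, 2 ** 31 - 1))
        sample = render_clip(params, T, H, W, seed=clip_seed,
                             subject_id=f"s{i:04d}",
                             labeled=(i in labeled_idx))
        samples.append(sample)
        all_params.append(params)
    if return_params:
        return samples, all_params
    return samples


# ---------------------------------------------------------------------------
# dataset persistence (PNG frames + manifest CSV)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "path", "label3", "label2", "split"]


def write_dataset(samples: list[GaitSample], out_dir: str | Path,
                  splits: dict[str, str] | None = None) -> Path:
    """One directory of PNG frames per subject plus ``manifest.csv``."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        frames = s.clip[0, 0]  # (T, H, W) gray
        for t in range(frames.shape[0]):
            iio.imwrite(sdir / f"frame_{t:04d}.png",
                        (frames[t] * 255).round().astype(np.uint8))
        rows.append({
            "subject_id": s.subject_id,
            "path": s.subject_id,
            "label3": "" if s.label3 is None else s.label3,
            "label2": "" if s.label2 is None else s.label2,
            "split": (splits or {}).get(s.subject_id, ""),
        })
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[GaitSample]:
    """Load a dataset written by :func:`write_dataset`."""
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    samples = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            sdir = root / row["path"]
            frame_files = sorted(sdir.glob("frame_*.png"))
            frames = np.stack(
                [iio.imread(f).astype(np.float32) / 255.0 for f in frame_files])
            label3 = int(row["label3"]) if row["label3"] else None
            samples.append(GaitSample(
                clip=frames[None, None], subject_id=row["subject_id"],
                label3=label3))
    return samples
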