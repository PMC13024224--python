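"""Video decoding, preprocessing, subject-level splitting, and augmentation.

Clips are 5-axis float arrays (B, C, T, H, W) with values in [0, 1]; the
full-scale protocol uses 16-frame clips center-cropped to 224x224, while
the desk-scale preset uses 8-frame 32x32 clips.  Crop windows follow a
0-based, half-open convention.

The teacher branch of Mean Teacher training sees *weak* augmentation
(light random translation, horizontal flip); the student branch sees
*strong* augmentation (random crop, color jitter, Gaussian noise, random
erasing, temporal jitter, speed perturbation).  At test time only the
center crop is applied — no test-time augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SplitAssignment",
    "AugmentConfig",
    "center_crop",
    "frames_to_clips",
    "subject_split",
    "weak_augment",
    "strong_augment",
    "load_video_frames",
    "clips_from_sample",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def center_crop(frames: np.ndarray, crop_size: int) -> np.ndarray:
    """Spatially centered crop of the last two axes.

    Offsets are ``floor((H - c) / 2)`` and ``floor((W - c) / 2)``; windows
    are half-open, e.g. a 224 crop of a 1440x2560 frame takes rows
    608..831 and columns 1168..1391 inclusive.
    """
    H, W = frames.shape[-2], frames.shape[-1]
    if H < crop_size or W < crop_size:
        raise ValueError(
            f"frame {H}x{W} smaller than crop {crop_size}; no implicit padding")
    r0 = (H - crop_size) // 2
    c0 = (W - crop_size) // 2
    return frames[..., r0:r0 + crop_size, c0:c0 + crop_size]


def frames_to_clips(frames: np.ndarray, clip_len: int = 16,
                    stride: int | None = None) -> list[np.ndarray]:
    """Group a (T, H, W) or (C, T, H, W) frame sequence into fixed-length
    clips of shape (1, C, clip_len, H, W).

    Windows start every ``stride`` frames (default: non-overlapping,
    stride = clip_len); a tail shorter than ``clip_len`` is dropped.  Fewer
    than ``clip_len`` frames yields an empty list.
    """
    if clip_len < 1:
        raise ValueError("clip_len must be >= 1")
    stride = clip_len if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if frames.ndim == 3:
        frames = frames[None]  # add channel axis
    C, T = frames.shape[0], frames.shape[1]
    clips = []
    for start in range(0, T - clip_len + 1, stride):
        clips.append(frames[None, :, start:start + clip_len])
    return clips


def clips_from_sample(clip: np.ndarray, clip_len: int,
                      stride: int | None = None) -> list[np.ndarray]:
    """Split a (1, C, T, H, W) video tensor into clip tensors."""
    return frames_to_clips(clip[0], clip_len, stride)


# ---------------------------------------------------------------------------
# subject-level split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """subject_id -> split name; every subject in exactly one split."""

    mapping: dict[str, str]

    SPLITS = ("train", "validation", "test")

    def subjects(self, split: str) -> list[str]:
        return [s for s, sp in self.mapping.items() if sp == split]

    def assert_disjoint(self) -> None:
        sets = [set(self.subjects(s)) for s in self.SPLITS]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"subject leakage between {self.SPLITS[i]} and "
                        f"{self.SPLITS[j]}: {sorted(overlap)[:5]}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subject_id,split\n")
            for sid, sp in self.mapping.items():
                fh.write(f"{sid},{sp}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SplitAssignment":
        mapping = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                sid, sp = line.strip().split(",")
                mapping[sid] = sp
        return cls(mapping)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def subject_split(subject_ids: list[str],
                  fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
                  seed: int = 0) -> SplitAssignment:
    """Random subject-level train/validation/test split.

    Validation and test counts are rounded half-away-from-zero; the
    remainder goes to train (100 subjects -> 64/16/20, 10 -> 6/2/2).
    Deterministic given the seed; duplicate ids are an error.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids")
    n = len(ids)
    n_val = _round_half_away(n * fractions[1])
    n_test = _round_half_away(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split fractions leave a negative partition")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    mapping = {}
    for sid in order[:n_train]:
        mapping[sid] = "train"
    for sid in order[n_train:n_train + n_val]:
        mapping[sid] = "validation"
    for sid in order[n_train + n_val:]:
        mapping[sid] = "test"
    out = SplitAssignment(mapping)
    out.assert_disjoint()
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes for the weak and strong augmentation branches.

    Defaults are stated at desk scale (32x32 frames); ``scaled(k)`` scales
    the pixel-valued offsets for larger inputs (the full-scale weak-crop
    default corresponds to 8 px at 224).
    """

    weak_max_shift: int = 1          # light random crop (translation), px
    weak_flip_prob: float = 0.5
    strong_max_shift: int = 3        # random crop (translation), px
    strong_flip_prob: float = 0.5
    brightness: float = 0.2          # multiplicative jitter in [1-b, 1+b]
    contrast: float = 0.2
    noise_sd: float = 0.03           # additive Gaussian noise
    erase_frac: float = 0.25         # max side of erased box, fraction of H
    erase_prob: float = 0.5
    temporal_jitter: int = 2         # start offset, frames
    speed_range: tuple[float, float] = (0.8, 1.25)

    def scaled(self, factor: float) -> "AugmentConfig":
        from dataclasses import replace
        return replace(self,
                       weak_max_shift=int(round(self.weak_max_shift * factor)),
                       strong_max_shift=int(round(self.strong_max_shift * factor)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _translate(clip: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift spatially with edge padding (crop-with-pad semantics)."""
    if dy == 0 and dx == 0:
        return clip
    H, W = clip.shape[-2:]
    pad_y, pad_x = abs(dy), abs(dx)
    padded = np.pad(clip, [(0, 0)] * (clip.ndim - 2) +
                    [(pad_y, pad_y), (pad_x, pad_x)], mode="edge")
    y0, x0 = pad_y + dy, pad_x + dx
    return padded[..., y0:y0 + H, x0:x0 + W]


def hflip(clip: np.ndarray) -> np.ndarray:
    """Horizontal flip (involution)."""
    return clip[..., ::-1].copy()


def weak_augment(clip: np.ndarray, seed,
                 config: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Teacher-branch augmentation: light random translation + flip."""
    rng = _as_rng(seed)
    out = np.asarray(clip, dtype=np.float32)
    s = config.weak_max_shift
    if s > 0:
        dy, dx = rng.integers(-s, s + 1, size=2)
        out = _translate(out, int(dy), int(dx))
    if rng.random() < config.weak_flip_prob:
        out = hflip(out)
    return np.clip(out, 0.0, 1.0)


def strong_augment(clip: np.ndarray, seed,
                   config: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Student-branch augmentation.

    Composition (fixed order): speed perturbation, temporal jitter, random
    crop (translation), horizontal flip, color jitter (brightness and
    contrast), Gaussian noise, random erasing.  Output shape equals input
    shape; values are clipped to [0, 1].  With all magnitudes zero the
    transform is the identity.
    """
    rng = _as_rng(seed)
    out = np.asarray(clip, dtype=np.float32)
    T = out.shape[-3]

    # speed perturbation: resample frame indices by a random factor
    lo, hi = config.speed_range
    if (lo, hi) != (1.0, 1.0):
        factor = rng.uniform(lo, hi)
        idx = np.clip(np.round(np.arange(T) * factor), 0, T - 1).astype(int)
        out = out[..., idx, :, :]

    # temporal jitter: shift the start frame, clamped at the ends
    if config.temporal_jitter > 0:
        off = int(rng.integers(-config.temporal_jitter,
                               config.temporal_jitter + 1))
        idx = np.clip(np.arange(T) + off, 0, T - 1)
        out = out[..., idx, :, :]

    s = config.strong_max_shift
    if s > 0:
        dy, dx = rng.integers(-s, s + 1, size=2)
        out = _translate(out, int(dy), int(dx))

    if rng.random() < config.strong_flip_prob:
        out = hflip(out)

    if config.brightness > 0:
        out = out * rng.uniform(1 - config.brightness, 1 + config.brightness)
    if config.contrast > 0:
        c = rng.uniform(1 - config.contrast, 1 + config.contrast)
        mean = out.mean()
        out = (out - mean) * c + mean

    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd,
                               size=out.shape).astype(np.float32)

    if config.erase_prob > 0 and rng.random() < config.erase_prob:
        H, W = out.shape[-2:]
        eh = int(rng.integers(1, max(2, int(config.erase_frac * H)) + 1))
        ew = int(rng.integers(1, max(2, int(config.erase_frac * W)) + 1))
        y0 = int(rng.integers(0, H - eh + 1))
        x0 = int(rng.integers(0, W - ew + 1))
        out = out.copy()
        out[..., y0:y0 + eh, x0:x0 + ew] = rng.random()

    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def load_video_frames(path: str | Path) -> np.ndarray:
    """Decode a video file (or a directory of PNG frames) to (T, H, W)
    grayscale float frames in [0, 1] at native frame rate."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = iio.imread(path)
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 4:  # (T, H, W, C) -> gray
        frames = frames.mean(axis=-1)
    if frames.max() > 1.0:
        frames = frames / 255.0
    return frames
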