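"""Spatial Hierarchical Pooling Module (SHPM).

SHPM replaces the terminal global pooling of a 3-D convolutional backbone.
A feature map ``X`` of shape ``(B, C, T, H, W)`` is partitioned, at each
pyramid level, into a grid of non-overlapping spatial blocks of size
``H_size x W_size`` (so ``H_bins = H / H_size`` and ``W_bins = W / W_size``,
which must divide evenly).  Each block contributes two statistics:

* ``mu[b, c, t, i, j]``  — the maximum over the block (prominent features),
* ``eta[b, c, t, i, j]`` — the mean over the block (average strength),

indexing block elements as ``X[b, c, t, i*H_size + h, j*W_size + w]``.
Per-frame statistics are then reduced over the temporal axis (mean by
default) and all levels are concatenated, in config order, into one feature
vector per sample.

Both a functional API (:func:`shpm_forward`, used in tests and analysis)
and a differentiable layer (:class:`SHPMLayer`, used inside the backbone)
are provided; the two share the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import Module

__all__ = [
    "SHPMConfig",
    "PooledFeature",
    "partition_bins",
    "block_pool",
    "shpm_forward",
    "SHPMLayer",
]


@dataclass(frozen=True)
class SHPMConfig:
    """Pyramid specification.

    Parameters
    ----------
    levels
        Ordered ``(H_size, W_size)`` block-size pairs.  Each size must
        divide the corresponding feature-map dimension.
    combine_mode
        ``"concat"`` keeps max and average statistics side by side;
        ``"sum"`` adds them (halving the vector length).
    temporal_mode
        ``"mean"`` (default) averages per-frame statistics over T;
        ``"max"`` takes the temporal maximum instead.
    """

    levels: tuple[tuple[int, int], ...] = ((8, 8), (4, 4), (2, 2))
    combine_mode: str = "concat"
    temporal_mode: str = "mean"

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("SHPMConfig needs at least one level")
        if self.combine_mode not in ("concat", "sum"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.temporal_mode not in ("mean", "max"):
            raise ValueError(f"unknown temporal_mode {self.temporal_mode!r}")
        object.__setattr__(
            self, "levels",
            tuple((int(h), int(w)) for h, w in self.levels))

    def vector_length(self, channels: int, H: int, W: int) -> int:
        factor = 2 if self.combine_mode == "concat" else 1
        total = 0
        for hs, ws in self.levels:
            hb, wb = partition_bins(H, W, hs, ws)
            total += channels * hb * wb * factor
        return total

    @classmethod
    def dyadic_for(cls, H: int, W: int, max_levels: int = 3,
                   **kwargs) -> "SHPMConfig":
        """Default pyramid: block sizes (H, W), (H/2, W/2), (H/4, W/4),
        keeping only levels whose sizes divide the map evenly."""
        levels = []
        for k in range(max_levels):
            hs, ws = H >> k, W >> k
            if hs >= 1 and ws >= 1 and H % hs == 0 and W % ws == 0:
                levels.append((hs, ws))
        if not levels:
            raise ValueError(f"no valid dyadic levels for map {H}x{W}")
        return cls(levels=tuple(levels), **kwargs)


@dataclass
class PooledFeature:
    """Per-level block statistics plus the flattened aggregate vector."""

    mu: list[np.ndarray]   # per level, shape (B, C, T, H_bins, W_bins)
    eta: list[np.ndarray]  # per level, same shapes
    vector: np.ndarray     # (B, D)
    levels: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def partition_bins(H: int, W: int, H_size: int, W_size: int) -> tuple[int, int]:
    """Number of spatial bins per axis; errors on non-divisible dimensions."""
    if H_size < 1 or W_size < 1:
        raise ValueError("block sizes must be >= 1")
    if H % H_size or W % W_size:
        raise ValueError(
            f"level ({H_size}, {W_size}) does not divide feature map "
            f"({H}, {W}); no implicit padding")
    return H // H_size, W // W_size


def _block_view(X: np.ndarray, H_size: int, W_size: int) -> np.ndarray:
    """Reshape (B,C,T,H,W) -> (B,C,T,H_bins,W_bins,H_size*W_size)."""
    B, C, T, H, W = X.shape
    hb, wb = partition_bins(H, W, H_size, W_size)
    Xr = X.reshape(B, C, T, hb, H_size, wb, W_size)
    return Xr.transpose(0, 1, 2, 3, 5, 4, 6).reshape(
        B, C, T, hb, wb, H_size * W_size)


def block_pool(X: np.ndarray, H_size: int, W_size: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Max (mu) and average (eta) statistics per spatial block.

    Returns arrays of shape ``(B, C, T, H_bins, W_bins)``.
    """
    if X.ndim != 5:
        raise ValueError("expected a 5-axis (B, C, T, H, W) tensor")
    blocks = _block_view(X, H_size, W_size)
    return blocks.max(axis=-1), blocks.mean(axis=-1)


def _temporal_reduce(a: np.ndarray, mode: str) -> np.ndarray:
    return a.mean(axis=2) if mode == "mean" else a.max(axis=2)


def shpm_forward(X: np.ndarray, config: SHPMConfig) -> PooledFeature:
    """Full SHPM: per-level block pooling, temporal reduction, aggregation.

    Vector layout per level: temporally-reduced ``mu`` flattened over
    (C, H_bins, W_bins) followed by ``eta`` likewise (``concat`` mode), or
    their sum (``sum`` mode); levels appear in config order.
    """
    mus, etas, parts = [], [], []
    B = X.shape[0]
    for hs, ws in config.levels:
        mu, eta = block_pool(X, hs, ws)
        mus.append(mu)
        etas.append(eta)
        mu_t = _temporal_reduce(mu, config.temporal_mode).reshape(B, -1)
        eta_t = _temporal_reduce(eta, config.temporal_mode).reshape(B, -1)
        if config.combine_mode == "concat":
            parts.append(np.concatenate([mu_t, eta_t], axis=1))
        else:
            parts.append(mu_t + eta_t)
    return PooledFeature(mu=mus, eta=etas,
                         vector=np.concatenate(parts, axis=1),
                         levels=config.levels)


class SHPMLayer(Module):
    """Differentiable SHPM: (B, C, T, H, W) -> (B, D) feature vector."""

    def __init__(self, config: SHPMConfig):
        super().__init__()
        self.config = config

    def forward(self, X: np.ndarray) -> np.ndarray:
        cfg = self.config
        B, C, T, H, W = X.shape
        self._in_shape = X.shape
        parts = []
        cache = []
        for hs, ws in cfg.levels:
            blocks = _block_view(X, hs, ws)
            amax = blocks.argmax(axis=-1)
            mu = np.take_along_axis(blocks, amax[..., None], axis=-1)[..., 0]
            eta = blocks.mean(axis=-1)
            if cfg.temporal_mode == "mean":
                mu_t, eta_t = mu.mean(axis=2), eta.mean(axis=2)
                tcache = None
            else:
                tmax_mu = mu.argmax(axis=2)
                tmax_eta = eta.argmax(axis=2)
                mu_t = np.take_along_axis(mu, tmax_mu[:, :, None], axis=2)[:, :, 0]
                eta_t = np.take_along_axis(eta, tmax_eta[:, :, None], axis=2)[:, :, 0]
                tcache = (tmax_mu, tmax_eta)
            cache.append((amax, mu.shape, tcache))
            mu_f, eta_f = mu_t.reshape(B, -1), eta_t.reshape(B, -1)
            if cfg.combine_mode == "concat":
                parts.append(np.concatenate([mu_f, eta_f], axis=1))
            else:
                parts.append(mu_f + eta_f)
        self._cache = cache
        return np.concatenate(parts, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cfg = self.config
        B, C, T, H, W = self._in_shape
        dX = np.zeros(self._in_shape, dtype=dy.dtype)
        offset = 0
        for (hs, ws), (amax, mu_shape, tcache) in zip(cfg.levels, self._cache):
            _, _, _, hb, wb = mu_shape
            n = C * hb * wb
            if cfg.combine_mode == "concat":
                dmu_t = dy[:, offset:offset + n].reshape(B, C, hb, wb)
                deta_t = dy[:, offset + n:offset + 2 * n].reshape(B, C, hb, wb)
                offset += 2 * n
            else:
                dmu_t = dy[:, offset:offset + n].reshape(B, C, hb, wb)
                deta_t = dmu_t
                offset += n
            # undo temporal reduction -> per-frame gradients
            if cfg.temporal_mode == "mean":
                dmu = np.broadcast_to(
                    dmu_t[:, :, None] / T, mu_shape).copy()
                deta = np.broadcast_to(
                    deta_t[:, :, None] / T, mu_shape).copy()
            else:
                tmax_mu, tmax_eta = tcache
                dmu = np.zeros(mu_shape, dtype=dy.dtype)
                deta = np.zeros(mu_shape, dtype=dy.dtype)
                np.put_along_axis(dmu, tmax_mu[:, :, None],
                                  dmu_t[:, :, None], axis=2)
                np.put_along_axis(deta, tmax_eta[:, :, None],
                                  deta_t[:, :, None], axis=2)
            # undo block pooling
            dblocks = np.zeros((B, C, T, hb, wb, hs * ws), dtype=dy.dtype)
            np.put_along_axis(dblocks, amax[..., None],
                              dmu[..., None], axis=-1)
            dblocks += (deta / (hs * ws))[..., None]
            dXr = dblocks.reshape(B, C, T, hb, wb, hs, ws)
            dX += dXr.transpose(0, 1, 2, 3, 5, 4, 6).reshape(
                B, C, T, H, W)
        self._cache = None
        return dX
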