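"""3-D residual backbone with SHPM head.

The network is the classic video ResNet layout: a convolutional stem, a
stack of residual stages built from two-conv basic blocks, then — instead
of global average pooling — the spatial hierarchical pooling module
feeding a single linear classification layer.

Two presets are provided:

* ``resnet18``: 4 stages x 2 blocks, channels (64, 128, 256, 512), for
  full-scale 16-frame 224x224 clips;
* ``tiny``: 2 stages x 1 block, channels (8, 16), for 8-frame 32x32 clips.
  Spatial stride-2 downsampling happens in the stem and in stage 2 only, so
  a 32x32 input leaves an 8x8 final map and the dyadic SHPM pyramid
  (1x1, 2x2, 4x4 bin grids) is nontrivial.

``feature_map`` exposes the last convolutional activations — the exact
tensor SHPM consumes and the Grad-CAM target layer.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn.layers import BasicBlock3d, BatchNorm3d, Conv3d, Module, ReLU
from .nn.optim import Adam
from .shpm import SHPMConfig, SHPMLayer, partition_bins
from .nn.layers import Linear

__all__ = ["BackboneConfig", "GaitBackbone", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters for :class:`GaitBackbone`."""

    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    num_classes: int = 3
    in_channels: int = 1
    stem_channels: int | None = None  # defaults to stage_channels[0]
    input_shape: tuple[int, int, int] = (16, 224, 224)  # (T, H, W)
    tiny: bool = False
    shpm: SHPMConfig | None = None  # None -> dyadic pyramid on the final map
    use_shpm: bool = True  # False -> global average pooling ablation

    @classmethod
    def resnet18(cls, num_classes: int = 3, in_channels: int = 1,
                 **kwargs) -> "BackboneConfig":
        return cls(num_classes=num_classes, in_channels=in_channels, **kwargs)

    @classmethod
    def make_tiny(cls, num_classes: int = 3, in_channels: int = 1,
                  input_shape: tuple[int, int, int] = (8, 32, 32),
                  **kwargs) -> "BackboneConfig":
        return cls(stage_channels=(8, 16), blocks_per_stage=(1, 1),
                   num_classes=num_classes, in_channels=in_channels,
                   input_shape=input_shape, tiny=True, **kwargs)

    def __post_init__(self):
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("stage_channels and blocks_per_stage mismatch")
        if len(self.stage_channels) < 2:
            raise ValueError("need at least 2 stages for a nontrivial SHPM map")

    def feature_map_shape(self) -> tuple[int, int, int, int]:
        """(C', T', H', W') of the last convolutional activations."""
        T, H, W = self.input_shape
        H, W = H // 2, W // 2  # stem spatial stride
        for i in range(1, len(self.stage_channels)):
            H, W = H // 2, W // 2
            if len(self.stage_channels) > 2:
                T = max(1, (T + 1) // 2)  # temporal stride in deep presets
        return self.stage_channels[-1], T, H, W


class GaitBackbone(Module):
    """3-D residual network with SHPM terminal pooling.

    Construction validates at build time that every SHPM level divides the
    final feature map, so divisibility can never fail mid-training.
    """

    def __init__(self, config: BackboneConfig, seed: int | None = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c0 = config.stem_channels or config.stage_channels[0]
        deep = len(config.stage_channels) > 2
        self.stem_conv = self.add_child(
            "stem_conv", Conv3d(config.in_channels, c0, 3, (1, 2, 2), 1,
                                rng=rng, compute_dx=False))
        self.stem_bn = self.add_child("stem_bn", BatchNorm3d(c0))
        self.stem_relu = self.add_child("stem_relu", ReLU())
        self.blocks: list[BasicBlock3d] = []
        c_in = c0
        for s, (c_out, n_blocks) in enumerate(
                zip(config.stage_channels, config.blocks_per_stage)):
            for b in range(n_blocks):
                if b == 0 and s > 0:
                    stride = (2, 2, 2) if deep else (1, 2, 2)
                else:
                    stride = 1
                blk = BasicBlock3d(c_in, c_out, stride, rng=rng)
                self.add_child(f"stage{s}_block{b}", blk)
                self.blocks.append(blk)
                c_in = c_out

        c_f, t_f, h_f, w_f = config.feature_map_shape()
        if h_f < 1 or w_f < 1 or t_f < 1:
            raise ValueError(
                f"input {config.input_shape} collapses to an empty feature map")
        if config.use_shpm:
            shpm_cfg = config.shpm or SHPMConfig.dyadic_for(h_f, w_f)
            for hs, ws in shpm_cfg.levels:
                partition_bins(h_f, w_f, hs, ws)  # build-time divisibility check
            self.shpm = self.add_child("shpm", SHPMLayer(shpm_cfg))
            d = shpm_cfg.vector_length(c_f, h_f, w_f)
        else:
            self.shpm = None
            d = c_f
        self.classifier = self.add_child(
            "classifier", Linear(d, config.num_classes, rng=rng))

    # -- forward paths -----------------------------------------------------
    def feature_map(self, clip: np.ndarray) -> np.ndarray:
        """Last-stage convolutional activations (B, C', T', H', W')."""
        x = np.asarray(clip, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError("clip must be (B, C, T, H, W)")
        x = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        for blk in self.blocks:
            x = blk(x)
        return x

    def head(self, feat: np.ndarray) -> np.ndarray:
        """Classifier on top of the feature map (the SHPM + linear path)."""
        if self.shpm is not None:
            vec = self.shpm(feat)
        else:
            self._gap_shape = feat.shape
            vec = feat.mean(axis=(2, 3, 4))
        return self.classifier(vec)

    def forward(self, clip: np.ndarray) -> np.ndarray:
        """Class logits (B, num_classes)."""
        return self.head(self.feature_map(clip))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dvec = self.classifier.backward(dlogits)
        if self.shpm is not None:
            dfeat = self.shpm.backward(dvec)
        else:
            B, C, T, H, W = self._gap_shape
            dfeat = np.broadcast_to(
                dvec[:, :, None, None, None] / (T * H * W),
                self._gap_shape).astype(dvec.dtype).copy()
        return self.backward_features(dfeat)

    def backward_features(self, dfeat: np.ndarray) -> np.ndarray:
        for blk in reversed(self.blocks):
            dfeat = blk.backward(dfeat)
        dfeat = self.stem_bn.backward(self.stem_relu.backward(dfeat))
        return self.stem_conv.backward(dfeat)

    def head_gradient(self, feat: np.ndarray, class_index: int) -> np.ndarray:
        """d(logit[class_index]) / d(feature_map), for saliency.

        Runs the head forward in eval mode on ``feat`` and backpropagates a
        one-hot seed through the classifier and pooling only.
        """
        was_training = self.training
        self.eval()
        logits = self.head(feat)
        seed = np.zeros_like(logits)
        seed[:, class_index] = 1.0
        dvec = self.classifier.backward(seed)
        if self.shpm is not None:
            dfeat = self.shpm.backward(dvec)
        else:
            B, C, T, H, W = self._gap_shape
            dfeat = np.broadcast_to(
                dvec[:, :, None, None, None] / (T * H * W),
                self._gap_shape).astype(dvec.dtype).copy()
        self.train(was_training)
        return dfeat

    def num_parameters(self) -> int:
        return sum(p.size for p in self.named_params().values())


def save_checkpoint(path: str | Path, model: GaitBackbone,
                    extra: dict | None = None) -> None:
    """Persist config + parameters + buffers (+ optional training state)."""
    payload = {
        "version": CHECKPOINT_VERSION,
        "config": model.config,
        "state": model.state_dict(),
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path) -> tuple[GaitBackbone, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version in {path}")
    model = GaitBackbone(payload["config"])
    model.load_state_dict(payload["state"])
    return model, payload.get("extra", {})
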