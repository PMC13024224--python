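"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases the gradient of its input from ``backward``.  Parameters and
gradients live in per-layer dicts keyed by name; a :class:`Module` tree
flattens them into a single ``{qualified_name: array}`` mapping so that an
optimizer or an exponential-moving-average copy can treat the whole network
as one flat parameter vector.

All arrays are float32 unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Linear",
    "BasicBlock3d",
    "Sequential",
]


class Module:
    """Base class: a node with local params/grads/buffers and named children."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    # -- tree plumbing -----------------------------------------------------
    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.params.items()}
        for name, child in self._children.items():
            out.update(child.named_params(prefix + name + "."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.grads.items()}
        for name, child in self._children.items():
            out.update(child.named_grads(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.buffers.items()}
        for name, child in self._children.items():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"param:" + k: v for k, v in self.named_params().items()}
        state.update({"buffer:" + k: v for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        buffers = self.named_buffers()
        for key, value in state.items():
            kind, _, name = key.partition(":")
            target = params if kind == "param" else buffers
            if name not in target:
                raise KeyError(f"unknown state entry {key!r}")
            target[name][...] = value

    def zero_grad(self) -> None:
        for m in self.modules():
            for k, p in m.params.items():
                m.grads[k] = np.zeros_like(p)

    def train(self, mode: bool = True) -> None:
        for m in self.modules():
            m.training = mode

    def eval(self) -> None:
        self.train(False)

    # -- interface ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected int or length-3 tuple, got {v!r}")
    return t


class Conv3d(Module):
    """3-D convolution (cross-correlation) via im2col + matmul.

    Input ``(B, C_in, T, H, W)`` -> output ``(B, C_out, T', H', W')`` with
    ``d' = (d + 2*pad - k) // stride + 1`` per axis.  He fan-out init.
    """

    def __init__(self, c_in: int, c_out: int, kernel=3, stride=1, pad=1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 compute_dx: bool = True):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        #: first-layer convolutions can skip the input gradient entirely
        self.compute_dx = compute_dx
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.pad = _triple(pad)
        rng = rng or np.random.default_rng()
        kt, kh, kw = self.kernel
        fan_out = c_out * kt * kh * kw
        std = np.sqrt(2.0 / fan_out)
        self.params["weight"] = rng.normal(
            0.0, std, size=(c_out, c_in, kt, kh, kw)).astype(np.float32)
        if bias:
            self.params["bias"] = np.zeros(c_out, dtype=np.float32)
        self._has_bias = bias

    def _cols(self, xp: np.ndarray) -> np.ndarray:
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        win = sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::st, ::sh, ::sw]  # (B,C,To,Ho,Wo,kt,kh,kw)
        return win

    def forward(self, x: np.ndarray) -> np.ndarray:
        pt, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        win = self._cols(xp)
        B, C, To, Ho, Wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            B * To * Ho * Wo, -1)
        w = self.params["weight"].reshape(self.c_out, -1)
        y = cols @ w.T
        if self._has_bias:
            y += self.params["bias"]
        self._cache = (cols, x.shape, xp.shape, (B, To, Ho, Wo))
        return y.reshape(B, To, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, (B, To, Ho, Wo) = self._cache
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.pad
        dyf = dy.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        self.grads["weight"] = (dyf.T @ cols).reshape(
            self.params["weight"].shape)
        if self._has_bias:
            self.grads["bias"] = dyf.sum(axis=0)
        if not self.compute_dx:
            self._cache = None
            return None
        # input gradient as a transposed convolution in gather form:
        # dilate dy by the stride, pad by (k - 1 - pad), correlate with the
        # spatially-flipped, channel-swapped kernel at stride 1.
        _, _, T, H, W = x_shape
        if (st, sh, sw) != (1, 1, 1):
            dyd = np.zeros((B, self.c_out, (To - 1) * st + 1,
                            (Ho - 1) * sh + 1, (Wo - 1) * sw + 1),
                           dtype=dy.dtype)
            dyd[:, :, ::st, ::sh, ::sw] = dy
        else:
            dyd = dy
        pt2, ph2, pw2 = kt - 1 - pt, kh - 1 - ph, kw - 1 - pw
        # residue frames/rows/cols the forward stride never reached
        et = T - (dyd.shape[2] + 2 * pt2 - kt + 1)
        eh = H - (dyd.shape[3] + 2 * ph2 - kh + 1)
        ew = W - (dyd.shape[4] + 2 * pw2 - kw + 1)
        dyp = np.pad(dyd, ((0, 0), (0, 0), (pt2, pt2 + et),
                           (ph2, ph2 + eh), (pw2, pw2 + ew)))
        wf = self.params["weight"][:, :, ::-1, ::-1, ::-1]
        wf = wf.transpose(1, 0, 2, 3, 4).reshape(self.c_in, -1)
        win = sliding_window_view(dyp, (kt, kh, kw), axis=(2, 3, 4))
        cols2 = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            B * T * H * W, -1)
        dx = (cols2 @ wf.T).reshape(B, T, H, W, self.c_in)
        self._cache = None
        return dx.transpose(0, 4, 1, 2, 3)


class BatchNorm3d(Module):
    """Per-channel batch normalization over (B, T, H, W).

    Running statistics are ordinary buffers; an EMA teacher copies them the
    same way it copies weights.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self.buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"][...] = (
                (1 - m) * self.buffers["running_mean"] + m * mean)
            self.buffers["running_var"][...] = (
                (1 - m) * self.buffers["running_var"] + m * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv)
        return self.params["gamma"].reshape(shape) * xhat + \
            self.params["beta"].reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        if not self.training:
            self._cache = None
            return dy * g * inv.reshape(shape)
        n = dy.size / dy.shape[1]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) \
            * inv.reshape(shape)
        self._cache = None
        return dx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Linear(Module):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng()
        if zero_init:
            w = np.zeros((d_out, d_in), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / d_in)
            w = rng.normal(0.0, std, size=(d_out, d_in)).astype(np.float32)
        self.params["weight"] = w
        self.params["bias"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dy.T @ self._x
        self.grads["bias"] = dy.sum(axis=0)
        dx = dy @ self.params["weight"]
        self._x = None
        return dx


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_child(str(i), layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class BasicBlock3d(Module):
    """Standard pre-activation-free residual block: conv-bn-relu-conv-bn (+skip)-relu."""

    def __init__(self, c_in: int, c_out: int, stride=1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = self.add_child(
            "conv1", Conv3d(c_in, c_out, 3, stride, 1, rng=rng))
        self.bn1 = self.add_child("bn1", BatchNorm3d(c_out))
        self.relu1 = self.add_child("relu1", ReLU())
        self.conv2 = self.add_child("conv2", Conv3d(c_out, c_out, 3, 1, 1, rng=rng))
        self.bn2 = self.add_child("bn2", BatchNorm3d(c_out))
        self.relu2 = self.add_child("relu2", ReLU())
        stride = _triple(stride)
        if stride != (1, 1, 1) or c_in != c_out:
            self.down_conv = self.add_child(
                "down_conv", Conv3d(c_in, c_out, 1, stride, 0, rng=rng))
            self.down_bn = self.add_child("down_bn", BatchNorm3d(c_out))
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.bn1(self.conv1(x))
        y = self.relu1(y)
        y = self.bn2(self.conv2(y))
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x))
        else:
            shortcut = x
        return self.relu2(y + shortcut)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu2.backward(dy)
        dmain = self.bn2.backward(dsum)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(dmain))
        if self.down_conv is not None:
            dshort = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dshort = dsum
        return dmain + dshort
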