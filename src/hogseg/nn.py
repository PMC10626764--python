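"""Minimal reverse-mode autograd over numpy arrays.

Implements exactly the operations the segmentation backbones and auxiliary
regression heads need — 2-D convolution, ReLU, 2×2 max-pooling (floor or
ceil mode), nearest-neighbour upsampling/resizing, channel concatenation,
linear maps, softmax cross-entropy and mean-squared-error — plus an Adam
optimizer. Feature maps are carried in NHWC layout internally (convolution
is evaluated as one GEMM per kernel offset, which avoids materializing
im2col patch matrices); the segmentation logits are transposed to the NCHW
contract at the model boundary.

Everything is single-threaded-deterministic; training trajectories
reproduce bit-for-bit for a fixed seed on one device. The working dtype is
float32 by default and can be switched to float64 (``set_dtype``) when
numerically validating gradients.

Gradients are accumulated by closures on a tape and released by a reverse
topological sweep from the loss tensor.
"""

from __future__ import annotations

import zlib
from typing import Callable, Sequence

import numpy as np

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global working dtype (float32 or float64)."""
    global _DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype


def get_dtype():
    return _DTYPE


class Tensor:
    """An array node in the autograd graph."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self.grad: np.ndarray | None = None
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def item(self) -> float:
        return float(self.data)

    # scalar algebra, enough for weighted loss sums
    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            _accum(self, out.grad)
            _accum(other, out.grad)

        out._backward = _bw
        return out

    def __mul__(self, scalar: float) -> "Tensor":
        s = float(scalar)
        out = Tensor(self.data * s, _prev=(self,))

        def _bw():
            _accum(self, out.grad * np.asarray(s, dtype=_DTYPE))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


class Parameter(Tensor):
    """A trainable tensor with a stable name for checkpointing."""

    __slots__ = ("name",)

    def __init__(self, data, name: str):
        super().__init__(data, requires_grad=True)
        self.name = name


def seeded_rng(seed: int, path: str) -> np.random.Generator:
    """RNG keyed by (global seed, layer path) so each layer's initialization
    is independent of every other layer's existence — adding or removing a
    head elsewhere in the model cannot perturb the backbone's weights."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(path.encode())])


# ---------------------------------------------------------------------------
# ops (feature maps are NHWC)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int = 0) -> Tensor:
    """2-D correlation, stride 1. x: (N, H, W, C); w: (kh, kw, C, F)."""
    kh, kw, C, F = w.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    N, Hp, Wp, _ = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    flat = xp.reshape(N * Hp * Wp, C)
    out_data = np.broadcast_to(b.data.astype(_DTYPE), (N, Ho, Wo, F)).copy()
    for i in range(kh):
        for j in range(kw):
            tmp = (flat @ w.data[i, j]).reshape(N, Hp, Wp, F)
            out_data += tmp[:, i:i + Ho, j:j + Wo, :]
    out = Tensor(out_data, _prev=(x, w, b))

    def _bw():
        g = np.ascontiguousarray(out.grad)
        gf = g.reshape(N * Ho * Wo, F)
        _accum(b, gf.sum(axis=0))
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, i:i + Ho, j:j + Wo, :].reshape(-1, C)
                dw[i, j] = xs.T @ gf
                if dxp is not None:
                    dxp[:, i:i + Ho, j:j + Wo, :] += (gf @ w.data[i, j].T
                                                      ).reshape(N, Ho, Wo, C)
        _accum(w, dw)
        if dxp is not None:
            _accum(x, dxp[:, p:Hp - p, p:Wp - p, :] if p else dxp)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _prev=(x,))

    def _bw():
        _accum(x, out.grad * mask)

    out._backward = _bw
    return out


def maxpool2d(x: Tensor, ceil_mode: bool = False) -> Tensor:
    """2×2 max-pool, stride 2, NHWC. Ceil mode pads odd edges with -inf so
    the output spatial size is ceil(s/2)."""
    N, H, W, C = x.data.shape
    if ceil_mode:
        Hp, Wp = -(-H // 2) * 2, -(-W // 2) * 2
        xp = np.full((N, Hp, Wp, C), -np.inf, dtype=_DTYPE)
        xp[:, :H, :W, :] = x.data
    else:
        Hp, Wp = (H // 2) * 2, (W // 2) * 2
        xp = x.data[:, :Hp, :Wp, :]
    Ho, Wo = Hp // 2, Wp // 2
    blocks = xp.reshape(N, Ho, 2, Wo, 2, C)
    m1 = blocks.max(axis=2)
    out = Tensor(m1.max(axis=3), _prev=(x,))

    def _bw():
        # route gradient to the (first) argmax of each 2x2 window
        dblocks = np.zeros_like(blocks)
        win = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(N, Ho, Wo, C, 4)
        idx = win.argmax(axis=-1)
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], out.grad[..., None], axis=-1)
        dblocks = dwin.reshape(N, Ho, Wo, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dxp = dblocks.reshape(N, Hp, Wp, C)
        if (Hp, Wp) == (H, W):
            _accum(x, dxp)
        else:
            dx = np.zeros_like(x.data)
            dx[:, :min(H, Hp), :min(W, Wp), :] = \
                dxp[:, :min(H, Hp), :min(W, Wp), :]
            _accum(x, dx)

    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling, NHWC."""
    out = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2), _prev=(x,))
    N, H, W, C = x.data.shape

    def _bw():
        _accum(x, out.grad.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)))

    out._backward = _bw
    return out


def resize_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour resize to an arbitrary spatial size, NHWC."""
    N, H, W, C = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    ri = (np.arange(out_h) * H) // out_h
    ci = (np.arange(out_w) * W) // out_w
    out = Tensor(x.data[:, ri[:, None], ci[None, :], :], _prev=(x,))

    def _bw():
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), ri[:, None], ci[None, :], slice(None)),
                  out.grad)
        _accum(x, dx)

    out._backward = _bw
    return out


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate NHWC tensors along the channel (last) axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            _accum(t, out.grad[..., a:b])

    out._backward = _bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    return a + b


def to_nchw(x: Tensor) -> Tensor:
    """Transpose NHWC → NCHW (used only at the model's output boundary)."""
    out = Tensor(np.ascontiguousarray(x.data.transpose(0, 3, 1, 2)), _prev=(x,))

    def _bw():
        _accum(x, out.grad.transpose(0, 2, 3, 1))

    out._backward = _bw
    return out


def flatten(x: Tensor) -> Tensor:
    N = x.data.shape[0]
    out = Tensor(x.data.reshape(N, -1), _prev=(x,))

    def _bw():
        _accum(x, out.grad.reshape(x.data.shape))

    out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (N, Din) @ w (Din, Dout) + b."""
    out = Tensor(x.data @ w.data + b.data, _prev=(x, w, b))

    def _bw():
        _accum(b, out.grad.sum(axis=0))
        _accum(w, x.data.T @ out.grad)
        _accum(x, out.grad @ w.data.T)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# losses


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel categorical cross-entropy.

    logits: (N, K, H, W); target: (N, H, W) integer class indices.
    """
    z = logits.data.astype(np.float64)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = z - zmax - np.log(sez)
    N, K, H, W = z.shape
    t = np.asarray(target)
    picked = np.take_along_axis(logp, t[:, None, :, :], axis=1)
    out = Tensor(-picked.mean(), _prev=(logits,))

    def _bw():
        p = ez / sez
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t[:, None, :, :], 1.0, axis=1)
        _accum(logits, (out.grad * (p - onehot) / (N * H * W)).astype(_DTYPE))

    out._backward = _bw
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error over all elements."""
    t = np.asarray(target, dtype=_DTYPE)
    diff = (pred.data - t).astype(np.float64)
    out = Tensor(np.mean(diff ** 2), _prev=(pred,))

    def _bw():
        _accum(pred, (out.grad * 2.0 * diff / diff.size).astype(_DTYPE))

    out._backward = _bw
    return out


def mean_tensors(tensors: Sequence[Tensor]) -> Tensor:
    """Unweighted mean of scalar tensors."""
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * (1.0 / len(tensors))


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class; submodules and parameters are discovered by attribute walk."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Parameter) and id(v) not in seen:
                seen.add(id(v))
                params.append(v)
            elif isinstance(v, Module):
                v._collect(params, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data = np.asarray(state[p.name], dtype=_DTYPE).copy()


class Conv2d(Module):
    """3×3 (or 1×1) convolution with He-style init seeded per layer path.

    Weights are stored (kh, kw, C, F); the draw is made in the canonical
    (F, C, kh, kw) order so a layer's initialization does not depend on the
    storage layout.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int,
                 seed: int, path: str):
        rng = seeded_rng(seed, path)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w.transpose(2, 3, 1, 0), name=f"{path}.weight")
        self.bias = Parameter(np.zeros(out_ch), name=f"{path}.bias")
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, seed: int, path: str):
        rng = seeded_rng(seed, path)
        std = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_dim, out_dim)),
                                name=f"{path}.weight")
        self.bias = Parameter(np.zeros(out_dim), name=f"{path}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class Adam:
    """Adam with framework-default betas/eps and no weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / b1t
            vh = self.v[i] / b2t
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.data.dtype)
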