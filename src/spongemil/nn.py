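"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numeric substrate for the MIL model: a tape-based ``Tensor``
with the handful of differentiable operations the architecture needs
(dense and convolutional layers, layer normalization, softmax attention),
plus an AdamW optimizer.  Everything runs in float64 on the CPU, which is
deliberate — bags at desk scale are small and exact reproducibility
matters more than throughput here.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# tensor core
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over broadcast dimensions back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data ** 2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(
                    np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other),
                            backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        return Tensor._make(self.data[index], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._prev))]
            visited.add(id(node))
            while stack:
                n, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in visited and child.requires_grad:
                        visited.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(n)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis: gamma * (x - mu) / sigma + beta."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    n = x.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            dx = (gx - gx.mean(axis=-1, keepdims=True)
                  - xhat * (gx * xhat).mean(axis=-1, keepdims=True)) * inv
            x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    assert c == c2, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, o, ho, wo))
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride]
            out += np.einsum("nchw,oc->nohw", xs, w.data[:, :, di, dj],
                             optimize=True)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for di in range(kh):
            for dj in range(kw):
                xs = xp[:, :, di:di + stride * ho:stride,
                        dj:dj + stride * wo:stride]
                if w.requires_grad:
                    w._accum_at(di, dj, np.einsum("nohw,nchw->oc", g, xs,
                                                  optimize=True))
                if dxp is not None:
                    dxp[:, :, di:di + stride * ho:stride,
                        dj:dj + stride * wo:stride] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, di, dj],
                            optimize=True)
        if dxp is not None:
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


# accumulate into a (di, dj) slice of a conv weight gradient
def _weight_accum_at(self: Tensor, di: int, dj: int, g: np.ndarray) -> None:
    if self.grad is None:
        self.grad = np.zeros_like(self.data)
    self.grad[:, :, di, dj] += g


Tensor._accum_at = _weight_accum_at  # type: ignore[attr-defined]


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0, "pool size must divide dims"
    view = x.data.reshape(n, c, h // k, k, w // k, k)
    out = view.mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(gg)

    return Tensor._make(out, (x,), backward)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0, "pool size must divide dims"
    view = x.data.reshape(n, c, h // k, k, w // k, k)
    out = view.max(axis=(3, 5))
    mask = view == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        if x.requires_grad:
            gg = (mask / counts) * g[:, :, :, None, :, None]
            x._accum(gg.reshape(x.shape))

    return Tensor._make(out, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def bce_with_logits(logit: Tensor, target: float, weight: float = 1.0) -> Tensor:
    """Numerically stable weighted binary cross-entropy from a logit scalar."""
    z = logit.data
    loss = weight * (np.maximum(z, 0.0) - z * target
                     + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        if logit.requires_grad:
            logit._accum(g * weight * (p - target))

    return Tensor._make(loss, (logit,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Parameter container with torch-like train/eval switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self) -> Iterable["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float64).reshape(p.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """3x3-style convolution with He or Dirac (near-identity) init.

    ``init="dirac"`` sets each output channel to pass through one input
    channel (center tap) plus small He noise — depth stays trainable while
    informative shallow features survive to the readout at initialization.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, init: str = "he"):
        super().__init__()
        scale = math.sqrt(2.0 / (c_in * k * k))
        weight = rng.normal(0.0, scale, (c_out, c_in, k, k))
        if init == "dirac":
            weight *= 0.1
            for o in range(c_out):
                weight[o, o % c_in, k // 2, k // 2] += 1.0
        self.weight = Tensor(weight, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention over a bag (no positional input).

    Treating the bag as an unordered set — no positional encodings — makes
    the whole model permutation-invariant in tile order, which downstream
    tests assert.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        k_len, _ = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(k_len, 3, h, hd).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (h, K, hd)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(k_len, h * hd)
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer (attention + feed-forward).

    Pre-norm keeps an unnormalized residual path from input to output, so
    per-tile identity is preserved through a deep stack at initialization;
    a post-norm stack of this depth progressively replaces every tile by
    the bag average and is untrainable at desk scale.
    """

    #: residual-branch output projections start near zero so each layer is
    #: close to identity at init; with uniform initial attention the branch
    #: otherwise replaces every tile by the bag mean, collapsing across-tile
    #: variance multiplicatively over the layer stack
    RESIDUAL_INIT_SCALE = 0.1

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, dropout_p: float = 0.1):
        super().__init__()
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.attn.proj.weight.data *= self.RESIDUAL_INIT_SCALE
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.ff2.weight.data *= self.RESIDUAL_INIT_SCALE
        self.norm2 = LayerNorm(dim)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        a = dropout(self.attn(self.norm1(x)), self.dropout_p, rng,
                    self.training)
        x = x + a
        f = self.ff2(self.ff1(self.norm2(x)).relu())
        f = dropout(f, self.dropout_p, rng, self.training)
        return x + f


class TinyCNN(Module):
    """Compact convolutional tile encoder for desk-scale experiments.

    An input 224 px RGB tile is average-pooled 8x (a goblet-cell blob is
    still several pixels wide at 28 px), passed through three conv-relu
    blocks with max-pooling, and read out by a spatial max per channel — a
    goblet-cell blob occupies a small fraction of a tile, and a max readout
    keeps its activation from being diluted by the surrounding tissue.  The
    last convolutional block ("conv3") is the saliency target layer.
    """

    POOL_IN = 8

    def __init__(self, rng: np.random.Generator, embed_dim: int = 64):
        super().__init__()
        self.embed_dim = embed_dim
        self.conv1 = Conv2d(3, 16, 3, rng, padding=1)
        self.conv1.weight.data = self._opponent_color_filters()
        self.conv2 = Conv2d(16, 32, 3, rng, padding=1, init="dirac")
        self.conv3 = Conv2d(32, embed_dim, 3, rng, padding=1, init="dirac")
        self.cache_activations = False
        self.activations: dict[str, Tensor] = {}

    @staticmethod
    def _opponent_color_filters() -> np.ndarray:
        """Generic low-level first-layer init: color-opponent smoothing and
        center-surround filters.

        Trained from slide labels alone, a from-scratch encoder has no
        pretrained low-level features to build on; seeding the first layer
        with the classic luminance/opponent-color basis (both signs, each
        as a 3x3 mean and a Laplacian) gives the optimizer discriminative
        color/contrast features from step one.  The layer remains trainable.
        """
        colors = np.array([
            [1.0, 1.0, 1.0],   # luminance
            [1.0, -1.0, 0.0],  # red-green
            [1.0, 0.0, -1.0],  # red-blue
            [0.0, 1.0, -1.0],  # green-blue
        ])
        colors /= np.linalg.norm(colors, axis=1, keepdims=True)
        mean3 = np.full((3, 3), 1.0 / 9.0)
        laplace = np.full((3, 3), -1.0 / 9.0)
        laplace[1, 1] = 8.0 / 9.0
        filters = []
        for color in colors:
            for spatial in (mean3, laplace):
                for sign in (1.0, -1.0):
                    filters.append(sign * color[:, None, None]
                                   * spatial[None, :, :] * 2.0)
        return np.stack(filters)

    def layer_names(self) -> list[str]:
        return ["conv1", "conv2", "conv3"]

    def __call__(self, x: Tensor) -> Tensor:
        """Encode tiles (N, 3, H, W) in [0, 1] to embeddings (N, embed_dim)."""
        x = avg_pool2d(x, self.POOL_IN)
        a1 = self.conv1(x).relu()
        x = max_pool2d(a1, 2)
        a2 = self.conv2(x).relu()
        x = max_pool2d(a2, 2)
        a3 = self.conv3(x).relu()
        if self.cache_activations:
            self.activations = {"conv1": a1, "conv2": a2, "conv3": a3}
        n, c, h, w = a3.shape
        return max_pool2d(a3, h).reshape(n, c)


class AttentionMILPooling(Module):
    """Attention-based MIL pooling: a_k = softmax_k(w^T tanh(V h_k)).

    ``V`` maps embeddings to a single hidden layer (default width 2048) and
    ``w`` projects to a scalar score per tile; the bag embedding is the
    attention-weighted sum of tile embeddings.  A gated variant
    (tanh * sigmoid) is available behind ``gated=True``.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 gated: bool = False):
        super().__init__()
        self.V = Linear(dim, hidden, rng, bias=False)
        self.w = Linear(hidden, 1, rng, bias=False)
        self.gated = gated
        if gated:
            self.U = Linear(dim, hidden, rng, bias=False)

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """Return (bag embedding (dim,), attention weights (K,))."""
        gate = self.V(h).tanh()
        if self.gated:
            gate = gate * self.U(h).sigmoid()
        scores = self.w(gate).reshape(-1)  # (K,)
        attn = softmax(scores, axis=-1)
        z = attn.reshape(1, -1) @ h  # (1, dim)
        return z.reshape(-1), attn


class AdamW(Module):
    """Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.1):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
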