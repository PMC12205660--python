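"""Minimal reverse-mode automatic differentiation core on numpy.

This is the numerical engine behind the spatiotemporal interaction network:
dense float32 tensors, a small set of differentiable primitives (matmul,
3-D convolution via im2col, softmax, layer normalization, ...), a light
module system, and an Adam optimizer.  It is written for desk-scale 3-D
patches (tens of thousands of voxels, batches of a few hundred), where
im2col + BLAS matmul is the fastest portable strategy on a single CPU.

Gradients are accumulated into ``Tensor.grad`` for every node reached by
``backward()``, which is what gradient-weighted class-activation mapping
needs (gradients at interior convolution activations, not only leaves).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv3d",
    "LayerNorm",
    "MultiHeadAttention",
    "Adam",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ---- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ---- shape ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            self._accum(g.reshape(src))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))

        def bw(g):
            self._accum(g.transpose(*inv))

        out._backward = bw
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)  # unbuffered: repeated indices accumulate
            self._accum(full)

        out._backward = bw
        return out

    # ---- reductions & nonlinearities --------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        src = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, src).astype(np.float32))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, src).astype(np.float32))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.float32(1.0 / n))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable class-weighted binary cross-entropy (mean)."""
    z = logits.data
    y = _as_f32(targets)
    w = np.ones_like(y) if weights is None else _as_f32(weights)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    val = np.float32((w * loss).sum() / w.size)
    out = Tensor(val, parents=(logits,))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * w * (s - y) / w.size)

    out._backward = bw
    return out


# ---- convolution ----------------------------------------------------------


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int):
    n, cin, d, h, wd = x.shape
    k = 3
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]  # (n, cin, do, ho, wo, k, k, k)
    do, ho, wo = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, cin * k * k * k)
    out = cols @ w + b  # w: (cin*27, cout)
    cout = w.shape[1]
    out = out.reshape(n, do, ho, wo, cout).transpose(0, 4, 1, 2, 3)
    return np.ascontiguousarray(out), cols, (n, cin, d, h, wd, do, ho, wo)


def _conv3d_backward(g: np.ndarray, cols: np.ndarray, w: np.ndarray, dims, stride: int,
                     pad: int, need_dx: bool = True):
    n, cin, d, h, wd, do, ho, wo = dims
    k = 3
    cout = w.shape[1]
    g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(n * do * ho * wo, cout)
    dw = cols.T @ g2
    db = g2.sum(axis=0)
    if not need_dx:
        return None, dw, db
    # col2im as 27 small GEMMs + strided adds (avoids one huge transpose)
    w_r = w.reshape(cin, k, k, k, cout)
    dxp = np.zeros((n, cin, d + 2 * pad, h + 2 * pad, wd + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                part = (g2 @ w_r[:, i, j, l, :].T).reshape(n, do, ho, wo, cin)
                dxp[:, :, i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    l : l + stride * wo : stride] += np.moveaxis(part, -1, 1)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return dxp, dw, db


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    out_data, cols, dims = _conv3d_forward(x.data, weight.data, bias.data, stride, pad)
    out = Tensor(out_data, parents=(x, weight, bias))

    def bw(g):
        dx, dw, db = _conv3d_backward(g, cols, weight.data, dims, stride, pad,
                                      need_dx=x.requires_grad)
        if dx is not None:
            x._accum(dx)
        if weight.requires_grad:
            weight._accum(dw)
        if bias.requires_grad:
            bias._accum(db)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            x._accum(dx.astype(np.float32))

    out._backward = bw
    return out


# ---- modules --------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module container: parameter discovery, train/eval mode, state I/O."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = _as_f32(a).copy()

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    """3x3x3 convolution, He-initialized, configurable stride, padding 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        fan_in = c_in * 27
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=1)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention over token sequences.

    Called as ``mha(q_x, kv_x)``; self-attention when both arguments are the
    same tensor.  The softmax weights of the last forward pass are kept on
    ``last_weights`` (head-major) for inspection.
    """

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % n_heads:
            raise ValueError("n_heads must divide embed_dim")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.wq = Linear(embed_dim, embed_dim, rng)
        self.wk = Linear(embed_dim, embed_dim, rng)
        self.wv = Linear(embed_dim, embed_dim, rng)
        self.wo = Linear(embed_dim, embed_dim, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor, n: int, t: int) -> Tensor:
        return x.reshape(n, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, q_x: Tensor, kv_x: Tensor) -> Tensor:
        n, tq, _ = q_x.shape
        tk = kv_x.shape[1]
        q = self._split(self.wq(q_x), n, tq)
        k = self._split(self.wk(kv_x), n, tk)
        v = self._split(self.wv(kv_x), n, tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * Tensor(np.float32(1.0 / np.sqrt(self.head_dim)))
        attn = scores.softmax(axis=-1)
        self.last_weights = attn.data.copy()
        out = attn @ v  # (n, heads, tq, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(n, tq, self.embed_dim)
        return self.wo(out)


class Adam:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
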