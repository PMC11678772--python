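"""Compact CPU neural-network layer framework on numpy.

Layer objects own their parameters and implement an explicit
``forward(x, train=...)`` / ``backward(grad)`` pair; a strict
forward-then-backward calling discipline lets each layer cache exactly the
activations its gradient needs.  Spectra are handled channels-last:
dense layers act on the trailing axis of ``(..., features)`` arrays and
convolutions on ``(batch, length, channels)`` arrays, so every contraction
lowers to one BLAS matmul.

Weight initialization is uniform over +-1/sqrt(fan_in) for dense and
convolutional layers (the conventional default for ReLU feed-forward
stacks), drawn from a seeded generator so identical (spec, seed) pairs give
identical initial parameters.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter discovery, state IO, call protocol."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj) -> None:
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def free_buffers(self) -> None:
        """Release cached work buffers (recursively) to bound memory."""
        seen: set[int] = set()

        def walk(obj) -> None:
            if isinstance(obj, Module):
                if id(obj) in seen:
                    return
                seen.add(id(obj))
                release = getattr(obj, "_release_buffers", None)
                if release is not None:
                    release()
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {a.shape}")
            p.value[...] = a


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    """Affine map on the trailing axis: ``y = x @ W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.n_in, self.n_out = n_in, n_out
        self.W = Parameter(_uniform_init(rng, (n_in, n_out), n_in, dtype))
        self.b = Parameter(_uniform_init(rng, (n_out,), n_in, dtype))
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        # flatten leading axes so the contraction is a single 2-D GEMM
        self._x = x
        x2 = x.reshape(-1, self.n_in)
        y = x2 @ self.W.value
        y += self.b.value
        return y.reshape(x.shape[:-1] + (self.n_out,))

    def backward(self, grad):
        x = self._x
        x2 = x.reshape(-1, self.n_in)
        g2 = grad.reshape(-1, self.n_out)
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return (g2 @ self.W.value.T).reshape(x.shape)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; identity when ``p == 0`` or in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype)
        self._mask /= keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Conv1d(Module):
    """1-D convolution over channels-last ``(batch, length, channels)`` input.

    ``padding='same'`` preserves length at stride 1; ``padding='causal'``
    pads only on the left (used by the temporal-convolution blocks).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        padding: str = "same",
        dtype=None,
    ):
        dtype = dtype or DEFAULT_DTYPE
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        span = (kernel - 1) * dilation
        if padding == "same":
            self.pad_left = span // 2
            self.pad_right = span - self.pad_left
        elif padding == "causal":
            self.pad_left, self.pad_right = span, 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        fan_in = c_in * kernel
        self.W = Parameter(_uniform_init(rng, (kernel, c_in, c_out), fan_in, dtype))
        self.b = Parameter(_uniform_init(rng, (c_out,), fan_in, dtype))
        # im2col work buffers, cached per batch geometry (small LRU) so that
        # alternating train/validation/remainder batch shapes do not force
        # hundreds of MB of re-allocation every step
        self._buffers: dict[tuple, tuple] = {}
        self._xp = self._cols = self._y = self._gcols = self._gxp = None

    def _release_buffers(self) -> None:
        self._buffers.clear()
        self._xp = self._cols = self._y = self._gcols = self._gxp = None

    def _w2(self) -> np.ndarray:  # (k*cin, cout) view of the kernel stack
        return self.W.value.reshape(self.kernel * self.c_in, self.c_out)

    def _ensure_buffers(self, B: int, L: int, dtype) -> None:
        key = (B, L, np.dtype(dtype))
        bufs = self._buffers.get(key)
        if bufs is None:
            Lp = L + self.pad_left + self.pad_right
            bufs = (
                np.zeros((B, Lp, self.c_in), dtype=dtype),
                np.empty((B, L, self.kernel, self.c_in), dtype=dtype),
                np.empty((B * L, self.c_out), dtype=dtype),
                np.empty((B * L, self.kernel * self.c_in), dtype=dtype),
                np.empty((B, Lp, self.c_in), dtype=dtype),
            )
            if len(self._buffers) >= 3:  # bound memory across geometries
                self._buffers.pop(next(iter(self._buffers)))
            self._buffers[key] = bufs
        else:  # LRU: move to the back
            self._buffers.pop(key)
            self._buffers[key] = bufs
        self._xp, self._cols, self._y, self._gcols, self._gxp = bufs

    def forward(self, x, train=False):
        # im2col: one (B*L, k*cin) @ (k*cin, cout) matmul per layer.
        # NOTE: the returned array is a reused buffer, valid until this
        # layer's next forward call; consumers must copy to retain it.
        B, L, _ = x.shape
        self._ensure_buffers(B, L, x.dtype)
        self._xp[:, self.pad_left:self.pad_left + L, :] = x
        for t in range(self.kernel):
            s = t * self.dilation
            self._cols[:, :, t, :] = self._xp[:, s:s + L, :]
        cols2 = self._cols.reshape(B * L, self.kernel * self.c_in)
        np.matmul(cols2, self._w2(), out=self._y)
        self._y += self.b.value
        return self._y.reshape(B, L, self.c_out)

    def backward(self, grad):
        B, L, _ = grad.shape
        g2 = grad.reshape(B * L, self.c_out)
        cols2 = self._cols.reshape(B * L, self.kernel * self.c_in)
        self.W.grad += (cols2.T @ g2).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        np.matmul(g2, self._w2().T, out=self._gcols)
        gcols = self._gcols.reshape(B, L, self.kernel, self.c_in)
        self._gxp[...] = 0.0
        for t in range(self.kernel):
            s = t * self.dilation
            self._gxp[:, s:s + L, :] += gcols[:, :, t, :]
        end = self._gxp.shape[1] - self.pad_right
        return self._gxp[:, self.pad_left:end, :]


class LayerNorm(Module):
    """Layer normalization over the trailing axis, with affine parameters."""

    def __init__(self, d: int, dtype=None, eps: float = 1e-5):
        dtype = dtype or DEFAULT_DTYPE
        self.d, self.eps = d, eps
        self.gamma = Parameter(np.ones(d, dtype=dtype))
        self.beta = Parameter(np.zeros(d, dtype=dtype))
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).reshape(-1, self.d).sum(axis=0)
        self.beta.grad += grad.reshape(-1, self.d).sum(axis=0)
        g = grad * self.gamma.value
        gmean = g.mean(axis=-1, keepdims=True)
        gx_mean = (g * xhat).mean(axis=-1, keepdims=True)
        return inv * (g - gmean - xhat * gx_mean)


def _softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention with ``h`` heads.

    Dropout is applied to the attention probabilities in training mode.
    No positional information is injected anywhere, so with dropout off the
    module is equivariant under permutation of the sequence axis.
    """

    def __init__(self, d: int, heads: int, rng: np.random.Generator,
                 p_drop: float = 0.0, dtype=None):
        if d % heads != 0:
            raise ValueError(f"embedding dim {d} not divisible by heads {heads}")
        self.d, self.heads, self.dh = d, heads, d // heads
        self.in_proj = Linear(d, 3 * d, rng, dtype=dtype)
        self.out_proj = Linear(d, d, rng, dtype=dtype)
        self.drop = Dropout(p_drop, rng=np.random.default_rng(rng.integers(2**31)))
        self._cache = None

    def _split(self, x):  # (B,T,d) -> (B,h,T,dh)
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,h,T,dh) -> (B,T,d)
        B, h, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)

    def forward(self, x, train=False):
        qkv = self.in_proj.forward(x, train=train)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)
        scale = 1.0 / np.sqrt(self.dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        probs = _softmax(scores)
        probs_d = self.drop.forward(probs, train=train)
        ctx = probs_d @ v
        self._cache = (q, k, v, probs, probs_d, scale)
        return self.out_proj.forward(self._merge(ctx), train=train)

    def backward(self, grad):
        q, k, v, probs, probs_d, scale = self._cache
        g_ctx = self._split(self.out_proj.backward(grad))
        g_probs_d = g_ctx @ v.transpose(0, 1, 3, 2)
        g_v = probs_d.transpose(0, 1, 3, 2) @ g_ctx
        g_probs = self.drop.backward(g_probs_d)
        # softmax backward: dS = P * (dP - sum(dP * P))
        g_scores = probs * (g_probs - (g_probs * probs).sum(axis=-1, keepdims=True))
        g_scores *= scale
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        g_qkv = np.concatenate(
            [self._merge(g_q), self._merge(g_k), self._merge(g_v)], axis=-1
        )
        return self.in_proj.backward(g_qkv)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention and feed-forward sublayers,
    each wrapped in residual + dropout + layer norm."""

    def __init__(self, d: int, heads: int, ff: int, rng: np.random.Generator,
                 p_drop: float = 0.1, dtype=None):
        self.attn = MultiHeadSelfAttention(d, heads, rng, p_drop=p_drop, dtype=dtype)
        self.drop1 = Dropout(p_drop, rng=np.random.default_rng(rng.integers(2**31)))
        self.norm1 = LayerNorm(d, dtype=dtype)
        self.ff1 = Linear(d, ff, rng, dtype=dtype)
        self.ff_relu = ReLU()
        self.ff_drop = Dropout(p_drop, rng=np.random.default_rng(rng.integers(2**31)))
        self.ff2 = Linear(ff, d, rng, dtype=dtype)
        self.drop2 = Dropout(p_drop, rng=np.random.default_rng(rng.integers(2**31)))
        self.norm2 = LayerNorm(d, dtype=dtype)

    def forward(self, x, train=False):
        a = self.drop1.forward(self.attn.forward(x, train=train), train=train)
        x1 = self.norm1.forward(x + a, train=train)
        f = self.ff1.forward(x1, train=train)
        f = self.ff_relu.forward(f, train=train)
        f = self.ff_drop.forward(f, train=train)
        f = self.ff2.forward(f, train=train)
        f = self.drop2.forward(f, train=train)
        return self.norm2.forward(x1 + f, train=train)

    def backward(self, grad):
        g = self.norm2.backward(grad)
        gf = self.drop2.backward(g)
        gf = self.ff2.backward(gf)
        gf = self.ff_drop.backward(gf)
        gf = self.ff_relu.backward(gf)
        gx1 = g + self.ff1.backward(gf)
        g1 = self.norm1.backward(gx1)
        ga = self.drop1.backward(g1)
        return g1 + self.attn.backward(ga)


class Reshape(Module):
    """Shape adapter (batch axis preserved implicitly via -1)."""

    def __init__(self, out_shape: tuple[int, ...]):
        self.out_shape = out_shape
        self._in_shape = None

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.out_shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Adam:
    """Adam optimizer with the conventional defaults (0.9, 0.999, 1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        # scratch arrays reused every step (avoids per-step allocation)
        self._s = [np.empty_like(p.value) for p in self.params]
        self._u = [np.empty_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        inv_sqrt_bc2 = 1.0 / np.sqrt(bc2)
        for p, m, v, s, u in zip(self.params, self.m, self.v, self._s, self._u):
            g = p.grad
            m *= b1
            np.multiply(g, 1.0 - b1, out=u)
            m += u
            np.multiply(g, g, out=u)
            u *= 1.0 - b2
            v *= b2
            v += u
            np.sqrt(v, out=s)
            s *= inv_sqrt_bc2
            s += self.eps
            np.multiply(m, self.lr / bc1, out=u)
            u /= s
            p.value -= u


def mse_value_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. ``pred``."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff
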