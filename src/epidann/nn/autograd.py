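"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray together with an optional gradient and the
closure that propagates gradients to its parents.  The op set is exactly what
the two-branch convolutional/recurrent network needs: broadcast arithmetic,
matmul, slicing, concatenation, the usual activations, 1-D valid convolution,
non-overlapping max pooling, a gradient-scaling pass-through (the gradient
reversal layer is ``grad_scale(x, -lam)``) and a clipped binary cross-entropy.

Gradients are accumulated (summed) when a tensor feeds several consumers.
dtype is preserved: training runs in float32, gradient-check tests in float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "sigmoid",
    "tanh",
    "conv1d",
    "maxpool1d",
    "grad_scale",
    "dropout",
    "binary_cross_entropy",
]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None, name=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name})"

    # -- graph mechanics -----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True).reshape(self.data.shape)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this node (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return _add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return _add(self, _scale(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return _add(_as_tensor(other), _scale(self, -1.0))

    def __mul__(self, other):
        return _mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return _scale(self, -1.0)

    def __matmul__(self, other):
        return _matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def reshape(self, *shape):
        return _reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self):
        return _sum(self)

    def mean(self):
        n = self.data.size
        return _scale(_sum(self), 1.0 / n)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs(*tensors):
    return any(t.requires_grad for t in tensors)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def _add(a, b):
    out = Tensor(a.data + b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def _mul(a, b):
    out = Tensor(a.data * b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def _scale(a, s):
    out = Tensor(a.data * s, requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    out._backward = backward
    return out


def _matmul(a, b):
    out = Tensor(a.data @ b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = backward
    return out


def _reshape(a, shape):
    out = Tensor(a.data.reshape(shape), requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def _getitem(a, idx):
    out = Tensor(a.data[idx], requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    out._backward = backward
    return out


def _sum(a):
    out = Tensor(np.asarray(a.data.sum(), dtype=a.data.dtype), requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    out._backward = backward
    return out


def concat(tensors, axis):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=_needs(*tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + n)
                t._accumulate(g[tuple(sl)])
            offset += n

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(a):
    out = Tensor(np.maximum(a.data, 0), requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = backward
    return out


def sigmoid(a):
    y = expit(a.data)
    out = Tensor(y.astype(a.data.dtype), requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data * (1 - out.data))

    out._backward = backward
    return out


def tanh(a):
    y = np.tanh(a.data)
    out = Tensor(y, requires_grad=a.requires_grad, _parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1 - out.data * out.data))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# network-specific ops
# ---------------------------------------------------------------------------

def conv1d(x, w, b=None):
    """Valid (no padding), stride-1 cross-correlation.

    x: (B, L, Cin); w: (K, Cin, Cout); b: (Cout,).  Returns (B, L-K+1, Cout).
    """
    B, L, cin = x.data.shape
    K, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv1d channel mismatch: input {cin}, kernel {cin_w}")
    if K > L:
        raise ValueError(f"kernel length {K} exceeds input length {L}")
    lout = L - K + 1
    # (B, Lout, Cin, K) view -> (B*Lout, K*Cin) columns (one fused copy)
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    cols = cols.transpose(0, 1, 3, 2).reshape(B * lout, K * cin)
    y = cols @ w.data.reshape(K * cin, cout)
    if b is not None:
        y += b.data
    out = Tensor(
        y.reshape(B, lout, cout),
        requires_grad=_needs(x, w) or (b is not None and b.requires_grad),
        _parents=(x, w) + ((b,) if b is not None else ()),
    )

    def backward(g):
        g2 = g.reshape(B * lout, cout)
        if w.requires_grad:
            w._accumulate((cols.T @ g2).reshape(K, cin, cout))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w.data.reshape(K * cin, cout).T).reshape(B, lout, K, cin)
            dx = np.zeros_like(x.data)
            for k in range(K):
                dx[:, k : k + lout, :] += dcols[:, :, k, :]
            x._accumulate(dx)

    out._backward = backward
    return out


def maxpool1d(x, pool, stride=None):
    """Non-overlapping max pooling along axis 1; trailing remainder dropped.

    Only ``stride == pool`` is supported (the architecture uses 20/20).
    """
    stride = pool if stride is None else stride
    if stride != pool:
        raise ValueError("maxpool1d supports stride == pool only")
    B, L, C = x.data.shape
    nf = L // pool
    if nf == 0:
        raise ValueError(f"input length {L} shorter than pool length {pool}")
    # (B, nf, C, pool) contiguous so the argmax runs along the fast axis;
    # argmax ties resolve to the leftmost window position
    blocks = np.ascontiguousarray(x.data[:, : nf * pool, :].reshape(B, nf, pool, C).transpose(0, 1, 3, 2))
    arg = blocks.argmax(axis=3)
    y = np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def backward(g):
        if x.requires_grad:
            dblocks = np.zeros_like(blocks)
            np.put_along_axis(dblocks, arg[..., None], g[..., None], axis=3)
            dx = np.zeros_like(x.data)
            dx[:, : nf * pool, :] = dblocks.transpose(0, 1, 3, 2).reshape(B, nf * pool, C)
            x._accumulate(dx)

    out._backward = backward
    return out


def grad_scale(x, factor):
    """Identity forward; multiplies the backward gradient by ``factor``.

    ``grad_scale(x, -lam)`` is the gradient reversal layer: the features it
    passes through are unchanged, but every gradient flowing back to the
    feature extractor is scaled by ``-lam``, so the extractor *ascends* the
    domain-discriminator loss while the discriminator itself descends it.
    """
    out = Tensor(x.data, requires_grad=x.requires_grad, _parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * factor)

    out._backward = backward
    return out


def dropout(x, rate, rng):
    """Inverted dropout: zero with probability ``rate``, scale kept by 1/(1-rate)."""
    if rate <= 0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return _mul(x, Tensor(mask.astype(x.data.dtype)))


def lstm_last_hidden(x, w, u, b):
    """Fused unidirectional LSTM returning the last hidden state.

    x: (B, T, C); w: (C, 4H); u: (H, 4H); b: (4H,).  Gate order (i, f, g, o).
    Forward caches gate activations per step; backward is handwritten
    backpropagation through time (verified against finite differences).
    """
    B, T, C = x.data.shape
    H = u.data.shape[0]
    dtype = x.data.dtype
    xp = x.data.reshape(B * T, C) @ w.data + b.data  # (B*T, 4H)
    xp = xp.reshape(B, T, 4 * H)
    gates = np.empty((T, B, 4 * H), dtype=dtype)  # post-activation i,f,g,o
    cs = np.empty((T, B, H), dtype=dtype)
    hs = np.empty((T, B, H), dtype=dtype)
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    for t in range(T):
        z = xp[:, t, :] + h @ u.data
        i = expit(z[:, :H])
        f = expit(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = expit(z[:, 3 * H :])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[t, :, :H], gates[t, :, H : 2 * H] = i, f
        gates[t, :, 2 * H : 3 * H], gates[t, :, 3 * H :] = g, o
        cs[t] = c
        hs[t] = h
    out = Tensor(h.astype(dtype, copy=False), requires_grad=_needs(x, w, u, b), _parents=(x, w, u, b))

    def backward(dh_last):
        dh = np.array(dh_last, dtype=dtype, copy=True)
        dc = np.zeros((B, H), dtype=dtype)
        dw = np.zeros_like(w.data)
        du = np.zeros_like(u.data)
        db = np.zeros_like(b.data)
        dx = np.zeros((B, T, C), dtype=dtype) if x.requires_grad else None
        dz = np.empty((B, 4 * H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i, f = gates[t, :, :H], gates[t, :, H : 2 * H]
            g, o = gates[t, :, 2 * H : 3 * H], gates[t, :, 3 * H :]
            tc = np.tanh(cs[t])
            dc = dc + dh * o * (1 - tc * tc)
            c_prev = cs[t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1 - g * g)
            dz[:, 3 * H :] = dh * tc * o * (1 - o)
            x_t = x.data[:, t, :]
            dw += x_t.T @ dz
            du += h_prev.T @ dz
            db += dz.sum(axis=0)
            if dx is not None:
                dx[:, t, :] = dz @ w.data.T
            dh = dz @ u.data.T
            dc = dc * f
        if w.requires_grad:
            w._accumulate(dw)
        if u.requires_grad:
            u._accumulate(du)
        if b.requires_grad:
            b._accumulate(db)
        if x.requires_grad:
            x._accumulate(dx)

    out._backward = backward
    return out


def binary_cross_entropy(prob, label, eps=1e-7, reduction="mean"):
    """Clipped binary cross-entropy -[y ln p + (1-y) ln(1-p)].

    ``prob`` is a Tensor of probabilities in [0, 1]; ``label`` a plain 0/1
    array.  Probabilities are clipped to [eps, 1-eps] before the log so the
    loss and its gradient stay finite.
    """
    y = np.asarray(label, dtype=prob.data.dtype)
    if y.shape != prob.data.shape:
        raise ValueError(f"label shape {y.shape} != prob shape {prob.data.shape}")
    p = np.clip(prob.data, eps, 1.0 - eps)
    losses = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    if reduction == "none":
        val = losses
    elif reduction == "sum":
        val = np.asarray(losses.sum(), dtype=prob.data.dtype)
    elif reduction == "mean":
        val = np.asarray(losses.mean(), dtype=prob.data.dtype)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = Tensor(val, requires_grad=prob.requires_grad, _parents=(prob,))

    def backward(g):
        if prob.requires_grad:
            dp = (p - y) / (p * (1 - p))
            if reduction == "mean":
                dp = dp / y.size
            prob._accumulate(np.broadcast_to(g, dp.shape) * dp if reduction != "none" else g * dp)

    out._backward = backward
    return out
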