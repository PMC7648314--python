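"""Trainable layers built on the autograd Tensor.

Initialization is Glorot-uniform with a dedicated RNG per layer, derived from
a single model seed and the layer's name.  That makes initialization of a
layer independent of which *other* layers exist, so model variants that share
an extractor (e.g. the full adversarial model and its adversary-free control)
start from bit-identical shared weights under the same seed.
"""

from __future__ import annotations

import zlib

import numpy as np

from .autograd import Tensor, lstm_last_hidden

__all__ = ["layer_rng", "Dense", "Conv1DLayer", "LSTM"]


def layer_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-layer RNG keyed by (seed, crc32(name))."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _glorot(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng, name="dense", dtype=np.float32):
        self.w = Tensor(_glorot(rng, (in_dim, out_dim), in_dim, out_dim, dtype), requires_grad=True, name=f"{name}.w")
        self.b = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True, name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class Conv1DLayer(Layer):
    """Valid 1-D convolution; weights (K, Cin, Cout)."""

    def __init__(self, in_channels, out_channels, kernel_len, rng, name="conv", dtype=np.float32):
        fan_in = kernel_len * in_channels
        fan_out = kernel_len * out_channels
        self.w = Tensor(
            _glorot(rng, (kernel_len, in_channels, out_channels), fan_in, fan_out, dtype),
            requires_grad=True,
            name=f"{name}.w",
        )
        self.b = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True, name=f"{name}.b")
        self.kernel_len = kernel_len

    def __call__(self, x: Tensor) -> Tensor:
        from .autograd import conv1d

        return conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class LSTM(Layer):
    """Unidirectional LSTM returning the last hidden state.

    Gate order along the 4H axis is (input, forget, cell, output); the forget
    gate bias starts at 1 (the usual convention that lets memory persist at
    initialization).  Input projections for every timestep are computed in a
    single matmul; the recurrence then only does one (B,H)x(H,4H) product per
    step.
    """

    def __init__(self, in_dim, hidden_dim, rng, name="lstm", dtype=np.float32):
        H = hidden_dim
        self.w = Tensor(_glorot(rng, (in_dim, 4 * H), in_dim, H, dtype), requires_grad=True, name=f"{name}.w")
        self.u = Tensor(_glorot(rng, (H, 4 * H), H, H, dtype), requires_grad=True, name=f"{name}.u")
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0
        self.b = Tensor(b, requires_grad=True, name=f"{name}.b")
        self.hidden_dim = H

    def __call__(self, x: Tensor) -> Tensor:
        return lstm_last_hidden(x, self.w, self.u, self.b)

    def parameters(self):
        return [self.w, self.u, self.b]
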