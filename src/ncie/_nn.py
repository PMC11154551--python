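"""Small neural building blocks (MLP, RNN cell, LSTM cell) on the autodiff core."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._autodiff import Adam, Tensor, concat

__all__ = ["Linear", "MLP", "RNNCell", "LSTMCell", "Adam", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP(Module):
    """Fully connected network, affine output.

    Hidden activation: ``tanh`` (smooth, used for statistics networks) or
    ``relu`` (piecewise-linear extrapolation, used for regression heads).
    """

    def __init__(self, rng: np.random.Generator, n_in: int,
                 hidden: Sequence[int], n_out: int,
                 activation: str = "tanh"):
        if activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(rng, dims[i], dims[i + 1])
                       for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x)
            x = x.tanh() if self.activation == "tanh" else x.relu()
        return self.layers[-1](x)

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class RNNCell(Module):
    """Plain tanh recurrence: H_t = tanh(x_t Wx + H_{t-1} Wh + b)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.Wx = Tensor(glorot(rng, n_in, n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, n_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(n_hidden), requires_grad=True)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        return (x @ self.Wx + h @ self.Wh + self.b).tanh()

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden)))

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


class LSTMCell(Module):
    """Standard LSTM; gate order in the fused weight is (i, f, g, o)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.Wx = Tensor(glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, state: tuple[Tensor, Tensor]
             ) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        h, c = state
        nh = self.n_hidden
        z = x @ self.Wx + h @ self.Wh + self.b
        i = z.slice_cols(0, nh).sigmoid()
        f = z.slice_cols(nh, 2 * nh).sigmoid()
        g = z.slice_cols(2 * nh, 3 * nh).tanh()
        o = z.slice_cols(3 * nh, 4 * nh).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, (h_new, c_new)

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z), Tensor(z.copy())

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]
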