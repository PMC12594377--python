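"""Neural-network building blocks on top of :mod:`gaitkinetics.autodiff`.

Layers follow the conventions of mainstream deep-learning libraries: modules
own :class:`~gaitkinetics.autodiff.Parameter` objects, expose
``parameters()`` / ``state_dict()`` and have a train/eval switch that
controls dropout and batch-norm statistics.  Everything is seeded through an
explicit ``numpy.random.Generator`` so that training runs are reproducible
bit for bit on one thread.
"""

from __future__ import annotations

import hashlib
import logging
import math
from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor, concat

logger = logging.getLogger("gaitkinetics")

__all__ = [
    "Module",
    "Linear",
    "Dropout",
    "BatchNorm",
    "BiLSTM",
    "Adam",
    "parameter_hash",
    "rmse_loss",
]


class Module:
    """Base class with parameter traversal and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    # -- traversal -----------------------------------------------------
    def parameters(self) -> Iterator[Parameter]:
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Parameter):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- mode ----------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation --------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All learnable arrays plus buffers, in deterministic order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(m.buffers())
        return arrays

    def buffers(self) -> list[np.ndarray]:
        return []

    def copy_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(
                f"state mismatch: expected {len(own)} arrays, got {len(arrays)}"
            )
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


def parameter_hash(module: Module, include_buffers: bool = True) -> str:
    """SHA-256 over every parameter (and buffer) byte — freeze contracts."""
    h = hashlib.sha256()
    arrays = (
        module.state_arrays()
        if include_buffers
        else [p.data for p in module.parameters()]
    )
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    """Affine map on the last axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_glorot(rng, in_features, out_features,
                                        (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expected last dim {self.in_features}, got {x.shape[-1]}"
            )
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout, active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm(Module):
    """Per-channel standardisation over batch and time of a [B,T,F] input.

    During training the batch statistics are used and folded into running
    estimates; in eval mode the running estimates are applied, so the
    transform seen at evaluation reproduces the training statistics.
    Zero-variance channels are clamped at ``eps`` with a logged warning.
    """

    eps = 1e-5

    def __init__(self, num_features: int, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.update_stats = True  # cleared when an encoder is frozen
        self._initialized = False
        self._warned_clamp = False

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.num_features:
            raise ValueError(
                f"BatchNorm expected {self.num_features} channels, got {x.shape[-1]}"
            )
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = ((x - mean) ** 2.0).mean(axis=axes)
            if np.any(var.data < self.eps) and not self._warned_clamp:
                logger.warning(
                    "BatchNorm: near-zero-variance channel clamped to eps "
                    "(reported once per layer)")
                self._warned_clamp = True
            if self.update_stats:
                m = 1.0 if not self._initialized else self.momentum
                self.running_mean[...] = (1 - m) * self.running_mean + m * mean.data
                self.running_var[...] = (1 - m) * self.running_var + m * var.data
                self._initialized = True
            var_c = Tensor(np.maximum(var.data, self.eps)) + (var - Tensor(var.data))
            xhat = (x - mean) * (var_c + self.eps) ** -0.5
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(np.maximum(self.running_var, self.eps))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class _LSTMDirection(Module):
    """One direction of one LSTM layer (gate order: i, f, g, o)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.w_ih = Parameter(_glorot(rng, input_size, 4 * hidden_size,
                                      (input_size, 4 * hidden_size)))
        self.w_hh = Parameter(_glorot(rng, hidden_size, 4 * hidden_size,
                                      (hidden_size, 4 * hidden_size)))
        bias = np.zeros(4 * hidden_size)
        bias[hidden_size:2 * hidden_size] = 1.0  # forget-gate bias
        self.bias = Parameter(bias)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        H = self.hidden_size
        # input projections for all frames at once
        xp = (x.reshape(B * T, F) @ self.w_ih + self.bias).reshape(B, T, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs = []
        for t in range(T):
            z = xp[:, t, :] + h @ self.w_hh
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h.reshape(B, 1, H))
        return concat(outputs, axis=1)


class BiLSTM(Module):
    """Stacked bidirectional LSTM with dropout after each layer.

    Output feature width is ``out_features`` (split evenly between the two
    directions, so it must be even).
    """

    def __init__(
        self,
        input_size: int,
        out_features: int,
        num_layers: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        if out_features % 2:
            raise ValueError("BiLSTM output width must be even")
        self.input_size = input_size
        self.out_features = out_features
        H = out_features // 2
        self.layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        self.dropouts: list[Dropout] = []
        size = input_size
        for _ in range(num_layers):
            fwd = _LSTMDirection(size, H, rng)
            bwd = _LSTMDirection(size, H, rng)
            self.layers.append((fwd, bwd))
            self.dropouts.append(Dropout(dropout, rng))
            size = out_features

    def parameters(self):
        for fwd, bwd in self.layers:
            yield from fwd.parameters()
            yield from bwd.parameters()

    def modules(self):
        yield self
        for fwd, bwd in self.layers:
            yield from fwd.modules()
            yield from bwd.modules()
        for d in self.dropouts:
            yield from d.modules()

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.input_size:
            raise ValueError(
                f"BiLSTM expected input width {self.input_size}, got {x.shape[-1]}"
            )
        out = x
        for (fwd, bwd), drop in zip(self.layers, self.dropouts):
            forward = fwd(out)
            backward = bwd(out.flip(1)).flip(1)
            out = drop(concat([forward, backward], axis=-1))
        return out


class Adam:
    """Adam optimizer; skips parameters whose ``trainable`` flag is off."""

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def rmse_loss(pred: Tensor, truth: Tensor) -> Tensor:
    """Root-mean-square error over all elements (the training loss)."""
    diff = pred - truth
    # tiny guard keeps the sqrt gradient finite at a perfect fit
    return ((diff * diff).mean() + 1e-24) ** 0.5
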