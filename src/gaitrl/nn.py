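"""Minimal feed-forward neural-network core on numpy.

Implements exactly what the actor-critic stack needs: dense multi-layer
perceptrons with ELU/ReLU/tanh activations, reverse-mode gradients computed
by hand, and the Adam optimizer. Parameters live in flat ``{name: ndarray}``
dictionaries so checkpointing is a plain ``npz`` round trip and "head
surgery" on a critic's output layer is direct array manipulation.

Shapes follow the row-batch convention: inputs are ``(B, d_in)``, weights
``(d_in, d_out)``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import ShapeError

Array = np.ndarray

# ---------------------------------------------------------------------------
# activations: value and derivative as a function of (pre-activation, output)


def _relu(z: Array) -> Array:
    return np.maximum(z, 0.0)


def _drelu(z: Array, h: Array) -> Array:
    return (z > 0.0).astype(z.dtype)


def _elu(z: Array) -> Array:
    return np.where(z > 0.0, z, np.expm1(z))


def _delu(z: Array, h: Array) -> Array:
    return np.where(z > 0.0, 1.0, h + 1.0)


def _tanh(z: Array) -> Array:
    return np.tanh(z)


def _dtanh(z: Array, h: Array) -> Array:
    return 1.0 - h * h


def _identity(z: Array) -> Array:
    return z


def _didentity(z: Array, h: Array) -> Array:
    return np.ones_like(z)


_ACT: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _drelu),
    "elu": (_elu, _delu),
    "tanh": (_tanh, _dtanh),
    "linear": (_identity, _didentity),
}


class MLP:
    """Dense multi-layer perceptron with hand-written backward pass.

    Parameters
    ----------
    sizes:
        Layer widths ``[d_in, h1, ..., d_out]``.
    hidden_activation:
        One of ``relu | elu | tanh`` applied after every layer but the last.
    rng:
        Source for weight initialization (He-style scaling).
    """

    def __init__(
        self,
        sizes: list[int],
        hidden_activation: str = "relu",
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        if len(sizes) < 2:
            raise ShapeError("MLP needs at least input and output sizes")
        if hidden_activation not in _ACT:
            raise ShapeError(f"unknown activation {hidden_activation!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.sizes = list(sizes)
        self.hidden_activation = hidden_activation
        self.n_layers = len(sizes) - 1
        self.params: dict[str, Array] = {}
        for i in range(self.n_layers):
            fan_in = sizes[i]
            scale = np.sqrt(2.0 / fan_in)
            self.params[f"W{i}"] = (
                rng.standard_normal((sizes[i], sizes[i + 1])) * scale
            ).astype(dtype)
            self.params[f"b{i}"] = np.zeros(sizes[i + 1], dtype=dtype)

    @property
    def in_dim(self) -> int:
        return self.sizes[0]

    @property
    def out_dim(self) -> int:
        return self.sizes[-1]

    def _act_for(self, layer: int) -> tuple[Callable, Callable]:
        if layer == self.n_layers - 1:
            return _ACT["linear"]
        return _ACT[self.hidden_activation]

    def forward(self, x: Array, cache: list | None = None) -> Array:
        """Forward pass; append per-layer tensors to ``cache`` if given."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.in_dim:
            raise ShapeError(
                f"expected input dim {self.in_dim}, got {x.shape[1]}"
            )
        h = x
        for i in range(self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            f, _ = self._act_for(i)
            out = f(z)
            if cache is not None:
                cache.append((h, z, out))
            h = out
        return h

    def backward(self, dout: Array, cache: list) -> tuple[dict[str, Array], Array]:
        """Reverse pass through a cached forward.

        Returns ``(grads, dx)`` where grads matches ``self.params`` keys and
        ``dx`` is the gradient with respect to the network input.
        """
        grads: dict[str, Array] = {}
        d = np.asarray(dout, dtype=np.float64)
        for i in range(self.n_layers - 1, -1, -1):
            h_in, z, h_out = cache[i]
            _, df = self._act_for(i)
            dz = d * df(z, h_out)
            grads[f"W{i}"] = h_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            d = dz @ self.params[f"W{i}"].T
        return grads, d

    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.sizes = list(self.sizes)
        clone.hidden_activation = self.hidden_activation
        clone.n_layers = self.n_layers
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


class Adam:
    """Adaptive-moment gradient descent on a flat parameter dictionary."""

    def __init__(
        self,
        params: dict[str, Array],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, Array]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def sync_new_params(self) -> None:
        """Register moment buffers for parameters added after construction."""
        for k, p in self.params.items():
            if k not in self.m or self.m[k].shape != p.shape:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)


def polyak_update(target: dict[str, Array], online: dict[str, Array], tau: float) -> None:
    """In-place soft update ``target <- (1 - tau) * target + tau * online``."""
    for k in target:
        target[k] *= 1.0 - tau
        target[k] += tau * online[k]
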