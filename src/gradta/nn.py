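"""Neural-network building blocks on top of the autodiff engine.

Weight initialisation is uniform scaled by fan-in (U(-1/sqrt(fan_in),
1/sqrt(fan_in))), drawn from a caller-supplied numpy Generator so that
model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def init_weight(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Minimal parameter container with train/eval mode propagation."""

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
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True) -> "Module":
        if hasattr(self, "training"):
            self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = init_weight(rng, (in_dim, out_dim), in_dim)
        self.bias = init_weight(rng, (out_dim,), in_dim) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Lookup table; row ``padding_idx`` is pinned to the zero vector."""

    def __init__(
        self,
        num_embeddings: int,
        dim: int,
        rng: np.random.Generator,
        padding_idx: int | None = None,
    ):
        table = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(num_embeddings, dim))
        if padding_idx is not None:
            table[padding_idx] = 0.0
        self.table = Tensor(table, requires_grad=True)
        if padding_idx is not None:
            # the optimizer keeps these rows frozen at zero
            self.table.name = "embedding"
            self.table.fixed_rows = (padding_idx,)  # type: ignore[attr-defined]
        self.padding_idx = padding_idx

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.table.take_rows(np.asarray(indices, dtype=np.int64))


class BatchNorm1d(Module):
    """Feature-wise batch normalisation with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=0, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.data.ravel()
            )
            n = x.shape[0]
            unbias = n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel() * unbias
            )
            norm = centered * ((var + self.eps) ** -0.5)
        else:
            norm = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return norm * self.gamma + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            fixed = getattr(p, "fixed_rows", None)
            if fixed is not None:
                g = g.copy()
                g[list(fixed)] = 0.0
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
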