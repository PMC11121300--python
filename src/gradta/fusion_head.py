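"""Attention-based fusion of drug and target representations plus the
fully connected prediction head and the MSE training loss.

The fusion network assigns one softmax weight per representation dimension:

    a_hat = U_a . ReLU(W_a (Y_d || Y_t))      (per-dimension scores)
    alpha = softmax(a_hat)                     (over the D dimensions)
    V     = alpha . (Y_d . Y_t)                (elementwise)

so different dimensions of a drug-target pair can contribute with
different strengths.  The head consumes (Y_d || Y_t || V), or just
(Y_d || Y_t) in the "no fusion" ablation, through two ReLU/dropout hidden
layers and a final scalar linear layer.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .nn import Linear, Module, dropout, init_weight


class PairRepresentation(NamedTuple):
    V: Tensor
    alpha: Tensor


class FusionParams(Module):
    """Per-dimension attention weights: U_a (D,), W_a (D, 2D)."""

    def __init__(self, repr_dim: int, rng: np.random.Generator):
        self.U_a = init_weight(rng, (repr_dim,), repr_dim)
        self.W_a = init_weight(rng, (repr_dim, 2 * repr_dim), 2 * repr_dim)
        self.repr_dim = repr_dim


def ann_fuse(y_d, y_t, p: FusionParams) -> PairRepresentation:
    """Fuse drug and target representations into the pair representation V.

    Accepts vectors (D,) or batches (B, D); alpha rows sum to 1.
    """
    y_d, y_t = as_tensor(y_d), as_tensor(y_t)
    if y_d.shape != y_t.shape or y_d.shape[-1] != p.repr_dim:
        raise ValueError(
            f"ann_fuse expects matching (.., {p.repr_dim}) inputs, "
            f"got {y_d.shape} and {y_t.shape}"
        )
    scores = p.U_a * (concat([y_d, y_t], axis=-1) @ p.W_a.T).relu()
    alpha = scores.softmax(axis=-1)
    return PairRepresentation(V=alpha * (y_d * y_t), alpha=alpha)


class PredictionHead(Module):
    """Two hidden fully connected layers (ReLU + dropout) and a scalar output."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, int] = (1024, 512),
        dropout_rate: float = 0.2,
        rng: np.random.Generator | None = None,
    ):
        if not (0.0 <= dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(in_dim, hidden[0], rng)
        self.fc2 = Linear(hidden[0], hidden[1], rng)
        self.out = Linear(hidden[1], 1, rng)
        self.dropout_rate = dropout_rate
        self.training = True

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if self.training and self.dropout_rate > 0 and rng is None:
            raise ValueError("training-mode head needs an rng for dropout masks")
        h = dropout(self.fc1(x).relu(), self.dropout_rate, rng, self.training)
        h = dropout(self.fc2(h).relu(), self.dropout_rate, rng, self.training)
        return self.out(h)


class FusionHead(Module):
    """ANN fusion + prediction head; ``use_ann=False`` drops the fusion
    branch and feeds the plain concatenation (the "no ANN" ablation)."""

    def __init__(
        self,
        repr_dim: int = 128,
        hidden: tuple[int, int] = (1024, 512),
        dropout_rate: float = 0.2,
        use_ann: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.use_ann = use_ann
        self.fusion = FusionParams(repr_dim, rng) if use_ann else None
        in_dim = (3 if use_ann else 2) * repr_dim
        self.head = PredictionHead(in_dim, hidden, dropout_rate, rng)
        self.training = True

    def __call__(
        self, y_d: Tensor, y_t: Tensor, rng: np.random.Generator | None = None
    ) -> Tensor:
        if self.use_ann:
            pair = ann_fuse(y_d, y_t, self.fusion)
            x = concat([y_d, y_t, pair.V], axis=-1)
        else:
            x = concat([y_d, y_t], axis=-1)
        return self.head(x, rng)


def predict_affinity(
    y_d, y_t, head: FusionHead, rng: np.random.Generator | None = None
) -> Tensor:
    """Scalar affinity prediction for one pair (or (B, 1) for batches)."""
    return head(as_tensor(y_d), as_tensor(y_t), rng)


def mse_loss(pred, actual) -> Tensor:
    """Mean squared error (1/n) sum (p_i - y_i)^2 as a differentiable scalar."""
    pred, actual = as_tensor(pred), as_tensor(actual)
    if pred.data.size == 0:
        raise ValueError("mse_loss requires at least one element")
    if pred.data.shape != actual.data.shape:
        raise ValueError("mse_loss: shape mismatch")
    diff = pred - actual
    return (diff * diff).mean()
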