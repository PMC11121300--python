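"""Protein encoder: embedding -> stacked BiGRU -> soft attention -> linear.

The encoded integer sequence is embedded per residue, passed through a
bidirectional gated recurrent network (forward and backward hidden states
concatenated per position), pooled with a position-wise soft-attention
mechanism, and projected to the target representation dimension D.

The gate equations are implemented exactly as bias-free forms

    z_t = sigmoid(x_t W_z + h_{t-1} U_z)
    r_t = sigmoid(x_t W_r + h_{t-1} U_r)
    h~_t = tanh(x_t W_x + (r_t . h_{t-1}) U_x)
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

with optional bias terms behind the ``gru_bias`` flag.  Note the update
convention: z_t gates the *candidate* state in, so all-zero weights give
h_t = 0.5 h_{t-1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concat, no_grad
from .featurize import PROTEIN_ALPHABET, ProteinEncoding
from .nn import Embedding, Linear, Module, init_weight


@dataclass
class GRUWeights:
    """One direction's gate weights; shapes (in_dim, hidden) / (hidden, hidden)."""

    W_z: Tensor
    U_z: Tensor
    W_r: Tensor
    U_r: Tensor
    W_x: Tensor
    U_x: Tensor
    b_z: Tensor | None = None
    b_r: Tensor | None = None
    b_x: Tensor | None = None

    @classmethod
    def create(
        cls, in_dim: int, hidden: int, rng: np.random.Generator, bias: bool = False
    ) -> "GRUWeights":
        def w(shape, fan):
            return init_weight(rng, shape, fan)

        return cls(
            W_z=w((in_dim, hidden), in_dim), U_z=w((hidden, hidden), hidden),
            W_r=w((in_dim, hidden), in_dim), U_r=w((hidden, hidden), hidden),
            W_x=w((in_dim, hidden), in_dim), U_x=w((hidden, hidden), hidden),
            b_z=w((hidden,), in_dim) if bias else None,
            b_r=w((hidden,), in_dim) if bias else None,
            b_x=w((hidden,), in_dim) if bias else None,
        )

    def tensors(self) -> list[Tensor]:
        out = [self.W_z, self.U_z, self.W_r, self.U_r, self.W_x, self.U_x]
        out += [b for b in (self.b_z, self.b_r, self.b_x) if b is not None]
        return out

    @property
    def hidden_dim(self) -> int:
        return self.U_z.shape[0]


@dataclass
class AttentionParams:
    """Score parameters: s(h) = U_a . tanh(W_a h); W_a is (score_dim, 2*hidden)."""

    U_a: Tensor
    W_a: Tensor

    @classmethod
    def create(cls, hidden2: int, score_dim: int, rng: np.random.Generator):
        return cls(
            U_a=init_weight(rng, (score_dim,), score_dim),
            W_a=init_weight(rng, (score_dim, hidden2), hidden2),
        )


class AttentionResult(NamedTuple):
    context: Tensor
    weights: Tensor


def gru_step(x_t, h_prev, w: GRUWeights) -> Tensor:
    """One gated-recurrence step; accepts vectors or (batch, dim) matrices."""
    x_t, h_prev = as_tensor(x_t), as_tensor(h_prev)
    if x_t.shape[-1] != w.W_z.shape[0] or h_prev.shape[-1] != w.U_z.shape[0]:
        raise ValueError(
            f"gru_step dimension mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"W_z {w.W_z.shape}"
        )
    zi = x_t @ w.W_z + h_prev @ w.U_z
    ri = x_t @ w.W_r + h_prev @ w.U_r
    if w.b_z is not None:
        zi, ri = zi + w.b_z, ri + w.b_r
    z, r = zi.sigmoid(), ri.sigmoid()
    ci = x_t @ w.W_x + (r * h_prev) @ w.U_x
    if w.b_x is not None:
        ci = ci + w.b_x
    h_cand = ci.tanh()
    return (1.0 - z) * h_prev + z * h_cand


def _run_direction(
    xs: list[Tensor], w: GRUWeights, mask: np.ndarray | None, reverse: bool
) -> list[Tensor]:
    """Run one direction over per-timestep inputs; masked steps hold state."""
    n_batch = xs[0].shape[0]
    hidden = w.hidden_dim
    h = Tensor(np.zeros((n_batch, hidden)))
    steps = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    states: list[Tensor] = [h] * len(xs)
    for t in steps:
        h_new = gru_step(xs[t], h, w)
        if mask is not None and not mask[:, t].all():
            m = Tensor(mask[:, t : t + 1])
            h = h_new * m + h * (1.0 - m)
        else:
            h = h_new
        states[t] = h
    return states


def bigru_encode(
    embedded,
    w_fwd: GRUWeights | Sequence[GRUWeights],
    w_bwd: GRUWeights | Sequence[GRUWeights],
) -> Tensor:
    """Encode an (L, D_in) sequence into (L, 2*hidden) hidden states.

    ``w_fwd``/``w_bwd`` may be single weight sets or per-layer sequences;
    stacked layers consume the concatenated states of the previous layer.
    Initial hidden states are zero in both directions.
    """
    embedded = as_tensor(embedded)
    if embedded.ndim != 2 or embedded.shape[0] == 0:
        raise ValueError("bigru_encode expects a non-empty (L, D) matrix")
    fwd = [w_fwd] if isinstance(w_fwd, GRUWeights) else list(w_fwd)
    bwd = [w_bwd] if isinstance(w_bwd, GRUWeights) else list(w_bwd)
    if len(fwd) != len(bwd):
        raise ValueError("need the same number of forward and backward layers")
    length = embedded.shape[0]
    xs = [embedded.take_rows(np.array([t])) for t in range(length)]
    for wf, wb in zip(fwd, bwd):
        f_states = _run_direction(xs, wf, None, reverse=False)
        b_states = _run_direction(xs, wb, None, reverse=True)
        xs = [concat([f, b], axis=1) for f, b in zip(f_states, b_states)]
    return concat(xs, axis=0)


def soft_attention(H, p: AttentionParams) -> AttentionResult:
    """Softmax-weighted sum of hidden states: alpha_i = softmax(U_a . tanh(W_a h_i))."""
    H = as_tensor(H)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("soft_attention expects a non-empty (L, D) matrix")
    scores = (H @ p.W_a.T).tanh() @ p.U_a
    if not np.all(np.isfinite(scores.data)):
        raise FloatingPointError("soft_attention: non-finite attention scores")
    alpha = scores.softmax(axis=-1)
    context = alpha @ H
    return AttentionResult(context=context, weights=alpha)


class TargetEncoder(Module):
    """Embedding + stacked BiGRU + soft attention + output projection.

    With ``use_attention=False`` the attention pool is replaced by a mean
    over valid positions before the projection (the "no attention" ablation
    variant).
    """

    def __init__(
        self,
        embed_dim: int = 128,
        hidden_dim: int = 128,
        layers: int = 2,
        repr_dim: int = 128,
        score_dim: int | None = None,
        gru_bias: bool = False,
        use_attention: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if layers < 1:
            raise ValueError("layers must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embedding = Embedding(
            len(PROTEIN_ALPHABET) + 1, embed_dim, rng, padding_idx=0
        )
        self.fwd: list[GRUWeights] = []
        self.bwd: list[GRUWeights] = []
        in_dim = embed_dim
        for _ in range(layers):
            self.fwd.append(GRUWeights.create(in_dim, hidden_dim, rng, bias=gru_bias))
            self.bwd.append(GRUWeights.create(in_dim, hidden_dim, rng, bias=gru_bias))
            in_dim = 2 * hidden_dim
        self.use_attention = use_attention
        self.attention = (
            AttentionParams.create(2 * hidden_dim, score_dim or hidden_dim, rng)
            if use_attention
            else None
        )
        self.out = Linear(2 * hidden_dim, repr_dim, rng)
        self.hidden_dim = hidden_dim
        self.repr_dim = repr_dim
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = self.embedding.parameters() + self.out.parameters()
        for w in self.fwd + self.bwd:
            params.extend(w.tensors())
        if self.attention is not None:
            params.extend([self.attention.U_a, self.attention.W_a])
        return params

    def forward_batch(self, index_rows: list[np.ndarray]) -> Tensor:
        """Encode a batch of trimmed index vectors into (B, repr_dim)."""
        lengths = np.array([max(len(r), 1) for r in index_rows])
        max_len = int(lengths.max())
        n_batch = len(index_rows)
        idx = np.zeros((n_batch, max_len), dtype=np.int64)
        for i, row in enumerate(index_rows):
            idx[i, : len(row)] = row
        mask = (np.arange(max_len)[None, :] < lengths[:, None]).astype(float)
        uniform = bool(mask.all())
        xs = [self.embedding(idx[:, t]) for t in range(max_len)]
        for wf, wb in zip(self.fwd, self.bwd):
            f_states = _run_direction(xs, wf, None if uniform else mask, False)
            b_states = _run_direction(xs, wb, None if uniform else mask, True)
            xs = [concat([f, b], axis=1) for f, b in zip(f_states, b_states)]
        if self.use_attention:
            scores = concat(
                [(h @ self.attention.W_a.T).tanh() @ self.attention.U_a.reshape(-1, 1)
                 for h in xs],
                axis=1,
            )
            if not uniform:
                scores = scores + Tensor(np.where(mask > 0, 0.0, -1e30))
            alpha = scores.softmax(axis=1)
            pooled = None
            for t, h in enumerate(xs):
                term = alpha.slice_cols(t, t + 1) * h
                pooled = term if pooled is None else pooled + term
        else:
            pooled = None
            inv_len = Tensor(1.0 / lengths[:, None])
            for t, h in enumerate(xs):
                term = h if uniform else Tensor(mask[:, t : t + 1]) * h
                pooled = term if pooled is None else pooled + term
            pooled = pooled * inv_len
        return self.out(pooled)

    def encode(self, enc: ProteinEncoding) -> Tensor:
        """Differentiable encoding of one protein into a repr_dim vector."""
        row = enc.indices[: enc.effective_length]
        return self.forward_batch([row]).reshape(-1)


def encode_target(enc: ProteinEncoding, encoder: TargetEncoder) -> np.ndarray:
    """Inference-mode target representation (deterministic)."""
    with no_grad():
        return encoder.encode(enc).data.copy()
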