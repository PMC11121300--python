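"""Drug encoder: stacked sample-and-aggregate (GraphSAGE) layers over the
molecular graph, global max pooling, and a ReLU-activated projection.

Each layer first summarises every atom's neighbourhood by the mean of the
ReLU-transformed neighbour embeddings,

    h_N(v) = mean_{u in N(v)} ReLU(W_pool h_u + b),

then updates the atom state from the concatenation of its own state with
that summary, h_v = ReLU(W_u [h_v || h_N(v)]), followed by batch
normalisation and another ReLU.  By default the full neighbourhood is
aggregated deterministically; fixed-size neighbour sampling with
replacement is available via ``sample_size`` for parity with large-graph
settings, though molecular graphs rarely need it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, as_tensor, concat, no_grad, segment_max, spmm
from .featurize import ATOM_FEATURE_DIM, MolecularGraph
from .nn import BatchNorm1d, Linear, Module, init_weight


@dataclass
class SageLayerParams:
    """Weights of one aggregation layer; W_pool/W_u stored as (out, in)."""

    W_pool: Tensor
    b: Tensor
    W_u: Tensor

    @classmethod
    def create(cls, in_dim: int, hidden: int, rng: np.random.Generator):
        return cls(
            W_pool=init_weight(rng, (hidden, in_dim), in_dim),
            b=init_weight(rng, (hidden,), in_dim),
            W_u=init_weight(rng, (hidden, in_dim + hidden), in_dim + hidden),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_pool, self.b, self.W_u]


def sage_aggregate(
    v: int,
    H_prev,
    g: MolecularGraph,
    p: SageLayerParams,
) -> Tensor:
    """Neighbourhood summary of atom ``v``: mean of ReLU(W_pool h_u + b).

    An isolated atom (no neighbours) yields the zero vector.
    """
    if not (0 <= v < g.n_atoms):
        raise ValueError(f"node {v} out of range for graph with {g.n_atoms} atoms")
    H_prev = as_tensor(H_prev)
    neigh = g.neighbors(v)
    if len(neigh) == 0:
        return Tensor(np.zeros(p.W_pool.shape[0]))
    transformed = (H_prev.take_rows(neigh) @ p.W_pool.T + p.b).relu()
    return transformed.mean(axis=0)


def sage_update(h_v, h_n, p: SageLayerParams) -> Tensor:
    """Updated atom state: ReLU(W_u (h_v || h_N))."""
    h_v, h_n = as_tensor(h_v), as_tensor(h_n)
    cat = concat([h_v, h_n], axis=-1)
    if cat.shape[-1] != p.W_u.shape[1]:
        raise ValueError(
            f"sage_update dimension mismatch: concat {cat.shape} vs W_u {p.W_u.shape}"
        )
    return (cat @ p.W_u.T).relu()


def mean_aggregation_matrix(
    g: MolecularGraph,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> sp.csr_matrix:
    """Row-stochastic (per non-isolated node) neighbour-averaging matrix.

    With ``sample_size`` Z, each node's row instead averages Z neighbours
    sampled with replacement (repeating when the degree is below Z).
    """
    n = g.n_atoms
    src, dst = g.edge_index
    if sample_size is None:
        mat = sp.csr_matrix(
            (np.ones(len(src)), (dst, src)), shape=(n, n)
        )
        deg = np.asarray(mat.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sp.diags(inv) @ mat
    if rng is None:
        raise ValueError("neighbour sampling requires a random generator")
    rows, cols, vals = [], [], []
    for v in range(n):
        neigh = src[dst == v]
        if len(neigh) == 0:
            continue
        picks = rng.choice(neigh, size=sample_size, replace=True)
        for u, c in zip(*np.unique(picks, return_counts=True)):
            rows.append(v)
            cols.append(u)
            vals.append(c / sample_size)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


class DrugEncoder(Module):
    """K stacked aggregation layers + batch norm + max-pool readout."""

    def __init__(
        self,
        layers: int = 3,
        hidden_dim: int = 128,
        repr_dim: int = 128,
        in_dim: int = ATOM_FEATURE_DIM,
        sample_size: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        if layers < 1:
            raise ValueError("layers must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.layers: list[SageLayerParams] = []
        self.norms: list[BatchNorm1d] = []
        dim = in_dim
        for _ in range(layers):
            self.layers.append(SageLayerParams.create(dim, hidden_dim, rng))
            self.norms.append(BatchNorm1d(hidden_dim))
            dim = hidden_dim
        self.out = Linear(hidden_dim, repr_dim, rng)
        self.sample_size = sample_size
        self.repr_dim = repr_dim
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer, norm in zip(self.layers, self.norms):
            params.extend(layer.tensors())
            params.extend(norm.parameters())
        params.extend(self.out.parameters())
        return params

    def forward_batch(
        self,
        node_features: np.ndarray,
        agg_matrix: sp.csr_matrix,
        segment_ids: np.ndarray,
        n_graphs: int,
    ) -> Tensor:
        """Encode a batch of graphs given stacked node features, the
        block-diagonal neighbour-averaging matrix and a node->graph map."""
        h = Tensor(node_features)
        for layer, norm in zip(self.layers, self.norms):
            pooled = spmm(agg_matrix, (h @ layer.W_pool.T + layer.b).relu())
            h = (concat([h, pooled], axis=1) @ layer.W_u.T).relu()
            h = norm(h).relu()
        pooled_graphs = segment_max(h, segment_ids, n_graphs)
        return self.out(pooled_graphs).relu()

    def node_embeddings(self, g: MolecularGraph) -> np.ndarray:
        """Final-layer per-atom embeddings (inference mode, no pooling)."""
        mat = mean_aggregation_matrix(g)
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                h = Tensor(g.node_features)
                for layer, norm in zip(self.layers, self.norms):
                    pooled = spmm(mat, (h @ layer.W_pool.T + layer.b).relu())
                    h = (concat([h, pooled], axis=1) @ layer.W_u.T).relu()
                    h = norm(h).relu()
                return h.data.copy()
        finally:
            self.train(was_training)

    def encode(self, g: MolecularGraph, rng: np.random.Generator | None = None) -> Tensor:
        """Differentiable encoding of one molecule into a repr_dim vector."""
        if g.n_atoms == 0:
            raise ValueError("cannot encode an empty molecular graph")
        mat = mean_aggregation_matrix(g, self.sample_size, rng)
        return self.forward_batch(
            g.node_features, mat, np.zeros(g.n_atoms, dtype=np.int64), 1
        ).reshape(-1)


def encode_drug(
    g: MolecularGraph,
    encoder: DrugEncoder,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inference-mode drug representation (deterministic without sampling)."""
    was_training = encoder.training
    encoder.eval()
    try:
        with no_grad():
            return encoder.encode(g, rng).data.copy()
    finally:
        encoder.train(was_training)
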