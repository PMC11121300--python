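"""Full affinity model: drug tower + target tower + fusion head.

Configuration defaults follow the tuned settings of the reference
hyperparameter grid: 128-dimensional embeddings/hidden states and
representations, 2 recurrent layers, 3 graph layers, dropout 0.2.  The
``tiny`` profile is a desk-scale configuration (all widths 32) used for
fast end-to-end experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, no_grad
from .drug_encoder import DrugEncoder, mean_aggregation_matrix
from .featurize import MolecularGraph, ProteinEncoding, encode_protein, smiles_to_graph
from .fusion_head import FusionHead
from .nn import Module
from .target_encoder import TargetEncoder


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 128          # amino-acid embedding width D_t
    target_hidden: int = 128      # hidden-state dimension per GRU direction
    bigru_layers: int = 2
    score_dim: int | None = None  # attention score space; None -> target_hidden
    drug_layers: int = 3
    drug_hidden: int = 128
    repr_dim: int = 128           # drug/target representation dimension D
    sample_size: int | None = None
    head_hidden: tuple[int, int] = (1024, 512)
    dropout: float = 0.2
    gru_bias: bool = False
    no_att: bool = False          # ablation: mean-pool instead of soft attention
    no_ann: bool = False          # ablation: concatenation-only pair representation

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile: width-32 towers, one recurrent layer, a small
        head, and no dropout (capacity checks want the bare model)."""
        cfg = cls(
            embed_dim=32, target_hidden=32, bigru_layers=1, drug_hidden=32,
            repr_dim=32, head_hidden=(64, 32), dropout=0.0,
        )
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "head_hidden" in d:
            d["head_hidden"] = tuple(d["head_hidden"])
        return cls(**d)


@dataclass
class GraphBatch:
    """Stacked node features + block-diagonal averaging matrix for a batch."""

    node_features: np.ndarray
    agg_matrix: sp.csr_matrix
    segment_ids: np.ndarray
    n_graphs: int


def build_graph_batch(
    graphs: list[MolecularGraph],
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> GraphBatch:
    feats = np.vstack([g.node_features for g in graphs])
    mats = [mean_aggregation_matrix(g, sample_size, rng) for g in graphs]
    seg = np.concatenate(
        [np.full(g.n_atoms, i, dtype=np.int64) for i, g in enumerate(graphs)]
    )
    return GraphBatch(
        node_features=feats,
        agg_matrix=sp.block_diag(mats, format="csr"),
        segment_ids=seg,
        n_graphs=len(graphs),
    )


class DTAModel(Module):
    """Drug-target affinity regressor combining the three modules."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.config = config
        self.target_encoder = TargetEncoder(
            embed_dim=config.embed_dim,
            hidden_dim=config.target_hidden,
            layers=config.bigru_layers,
            repr_dim=config.repr_dim,
            score_dim=config.score_dim,
            gru_bias=config.gru_bias,
            use_attention=not config.no_att,
            rng=rng,
        )
        self.drug_encoder = DrugEncoder(
            layers=config.drug_layers,
            hidden_dim=config.drug_hidden,
            repr_dim=config.repr_dim,
            sample_size=config.sample_size,
            rng=rng,
        )
        self.fusion = FusionHead(
            repr_dim=config.repr_dim,
            hidden=config.head_hidden,
            dropout_rate=config.dropout,
            use_ann=not config.no_ann,
            rng=rng,
        )
        self.training = True

    # -- forward --------------------------------------------------------

    def forward_batch(
        self,
        graph_batch: GraphBatch,
        drug_inverse: np.ndarray,
        index_rows: list[np.ndarray],
        target_inverse: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predict (B, 1) affinities; unique entities are encoded once and
        gathered to pairs via the inverse index arrays."""
        y_d = self.drug_encoder.forward_batch(
            graph_batch.node_features,
            graph_batch.agg_matrix,
            graph_batch.segment_ids,
            graph_batch.n_graphs,
        ).take_rows(drug_inverse)
        y_t = self.target_encoder.forward_batch(index_rows).take_rows(target_inverse)
        return self.fusion(y_d, y_t, rng)

    def predict_pairs(
        self,
        graphs: list[MolecularGraph],
        encodings: list[ProteinEncoding],
        chunk_size: int = 512,
    ) -> np.ndarray:
        """Inference-mode predictions for aligned lists of featurized pairs."""
        if len(graphs) != len(encodings):
            raise ValueError("graphs and encodings must be aligned")
        was_training = self.training
        self.eval()
        out = np.empty(len(graphs))
        try:
            with no_grad():
                for start in range(0, len(graphs), chunk_size):
                    gs = graphs[start : start + chunk_size]
                    es = encodings[start : start + chunk_size]
                    gb = build_graph_batch(gs)
                    rows = [e.indices[: max(e.effective_length, 1)] for e in es]
                    pred = self.forward_batch(
                        gb,
                        np.arange(len(gs)),
                        rows,
                        np.arange(len(es)),
                    )
                    out[start : start + len(gs)] = pred.data.ravel()
        finally:
            self.train(was_training)
        return out

    def predict(self, smiles: str, sequence: str) -> float:
        """Convenience single-pair prediction from raw SMILES and sequence."""
        return float(
            self.predict_pairs([smiles_to_graph(smiles)], [encode_protein(sequence)])[0]
        )

    # -- serialization --------------------------------------------------

    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for norm in self.drug_encoder.norms:
            arrays.extend([norm.running_mean, norm.running_var])
        return arrays

    def save(self, path) -> None:
        """Checkpoint: an .npz of all weights plus a JSON config sidecar."""
        path = Path(path)
        np.savez(
            path,
            config=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            **{f"arr_{i}": a for i, a in enumerate(self._state_arrays())},
        )

    @classmethod
    def load(cls, path) -> "DTAModel":
        with np.load(Path(path), allow_pickle=False) as archive:
            config = ModelConfig.from_dict(
                json.loads(bytes(archive["config"]).decode())
            )
            model = cls(config)
            state = model._state_arrays()
            for i, arr in enumerate(state):
                loaded = archive[f"arr_{i}"]
                if loaded.shape != arr.shape:
                    raise ValueError("checkpoint does not match model configuration")
                arr[...] = loaded
        return model

    def copy_weights_from(self, arrays: list[np.ndarray]) -> None:
        for dst, src in zip(self._state_arrays(), arrays):
            dst[...] = src

    def snapshot_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays()]
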