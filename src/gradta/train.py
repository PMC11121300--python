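"""Training loop, evaluation and candidate-ranking workflows.

Training minimises the MSE loss with Adam (learning rate 2e-4 by default,
600 epochs, batch 128/256 for the small/large profiles).  Everything that
draws randomness — weight initialisation, batch shuffling, dropout masks,
optional neighbour sampling — is derived from one integer seed, so a run
is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import featurize
from .autodiff import Tensor
from .data import AffinityDataset
from .fusion_head import mse_loss
from .metrics import MetricsReport, metrics_report
from .model import DTAModel, ModelConfig, build_graph_batch
from .nn import Adam
from .splits import Split

logger = logging.getLogger(__name__)

PROFILES = {"small": 128, "large": 256}


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 600
    batch_size: int = 128
    learning_rate: float = 2e-4
    seed: int = 0
    eval_every: int = 10          # validation cadence (epochs), if a val set exists
    select: str = "final"         # "final" or "best" validation checkpoint
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.select not in ("final", "best"):
            raise ValueError("select must be 'final' or 'best'")

    @classmethod
    def profile(cls, name: str, **overrides) -> "TrainConfig":
        return replace(cls(batch_size=PROFILES[name]), **overrides)

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Desk-scale profile: larger steps, fewer epochs, one big batch
        budget-matched to synthetic datasets of a few hundred pairs."""
        return replace(
            cls(epochs=200, batch_size=256, learning_rate=1e-3), **overrides
        )


@dataclass
class TrainResult:
    model: DTAModel
    history: list[dict] = field(default_factory=list)
    train_config: TrainConfig | None = None

    @property
    def final_train_loss(self) -> float:
        return self.history[-1]["train_loss"]


class _FeatureCache:
    """Featurize each unique drug/target once per run."""

    def __init__(self, ds: AffinityDataset):
        self.graphs = {did: featurize.smiles_to_graph(s) for did, s in ds.drugs.items()}
        self.rows = {}
        for tid, seq in ds.targets.items():
            enc = featurize.encode_protein(seq)
            self.rows[tid] = enc.indices[: max(enc.effective_length, 1)]


def _batch_forward(model, cache, ds, indices, rng):
    """Forward one batch of record indices; returns (pred, y) tensors."""
    recs = [ds.records[i] for i in indices]
    drug_ids = [r.drug_id for r in recs]
    target_ids = [r.target_id for r in recs]
    uniq_d, inv_d = np.unique(drug_ids, return_inverse=True)
    uniq_t, inv_t = np.unique(target_ids, return_inverse=True)
    gb = build_graph_batch(
        [cache.graphs[d] for d in uniq_d], model.config.sample_size, rng
    )
    rows = [cache.rows[t] for t in uniq_t]
    pred = model.forward_batch(gb, inv_d, rows, inv_t, rng)
    y = Tensor(np.array([r.affinity for r in recs])[:, None])
    return pred, y


def train(
    ds: AffinityDataset,
    split: Split,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Fit the model on ``split.train``, optionally tracking validation
    metrics, and return the trained model with a per-epoch loss log."""
    train_idx = np.asarray(split.train)
    if train_idx.size == 0:
        raise ValueError("empty training set")
    if train_idx.max(initial=-1) >= len(ds):
        raise ValueError("split indices out of range for dataset")

    seeds = np.random.SeedSequence(train_config.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    shuffle_rng = np.random.default_rng(seeds[1])
    dropout_rng = np.random.default_rng(seeds[2])

    model = DTAModel(model_config, seed=init_seed)
    cache = _FeatureCache(ds)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    has_val = len(split.validation) > 0
    best_val, best_weights = np.inf, None
    history: list[dict] = []

    for epoch in range(1, train_config.epochs + 1):
        model.train()
        perm = shuffle_rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), train_config.batch_size):
            batch = perm[start : start + train_config.batch_size]
            pred, y = _batch_forward(model, cache, ds, batch, dropout_rng)
            loss = mse_loss(pred, y)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting at {start}): {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}

        if has_val and (
            epoch % train_config.eval_every == 0 or epoch == train_config.epochs
        ):
            report = evaluate(model, ds, split.validation, cache=cache)
            entry["val_mse"] = report.mse
            entry["val_ci"] = report.ci
            if report.mse < best_val:
                best_val = report.mse
                if train_config.select == "best":
                    best_weights = model.snapshot_weights()
        history.append(entry)
        if epoch % train_config.log_every == 0 or epoch == train_config.epochs:
            logger.info("epoch %d: %s", epoch, entry)

    if train_config.select == "best" and best_weights is not None:
        model.copy_weights_from(best_weights)
    model.eval()
    return TrainResult(model=model, history=history, train_config=train_config)


def predict_indices(
    model: DTAModel,
    ds: AffinityDataset,
    indices,
    cache: _FeatureCache | None = None,
) -> np.ndarray:
    cache = cache or _FeatureCache(ds)
    indices = np.asarray(indices)
    graphs = [cache.graphs[ds.records[i].drug_id] for i in indices]
    encs = [
        featurize.ProteinEncoding(
            indices=np.pad(
                cache.rows[ds.records[i].target_id],
                (0, featurize.PROTEIN_ENCODED_LENGTH
                 - len(cache.rows[ds.records[i].target_id])),
            ),
            original_length=len(cache.rows[ds.records[i].target_id]),
        )
        for i in indices
    ]
    return model.predict_pairs(graphs, encs)


def evaluate(
    model: DTAModel,
    ds: AffinityDataset,
    indices,
    cache: _FeatureCache | None = None,
) -> MetricsReport:
    """Inference-mode metrics (MSE, CI, rm², Spearman) on the given records."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("cannot evaluate on an empty index set")
    pred = predict_indices(model, ds, indices, cache)
    y = np.array([ds.records[i].affinity for i in indices])
    return metrics_report(y, pred)


def run_repeats(
    ds: AffinityDataset,
    split_fn,
    model_config: ModelConfig,
    train_config: TrainConfig,
    repeats: int = 5,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Repeat (split -> train -> test) with seeds seed+0..repeats-1 and
    report per-repeat metrics plus their field-wise mean."""
    reports = []
    for r in range(repeats):
        seed = train_config.seed + r
        split = split_fn(seed)
        result = train(ds, split, model_config, replace(train_config, seed=seed))
        reports.append(evaluate(result.model, ds, split.test))
    mean = MetricsReport(
        mse=float(np.mean([r.mse for r in reports])),
        ci=float(np.mean([r.ci for r in reports])),
        rm2=float(np.mean([r.rm2 for r in reports])),
        spearman=float(np.mean([r.spearman for r in reports])),
        n=int(np.sum([r.n for r in reports])),
    )
    return reports, mean


@dataclass
class RankingResult:
    ranking: list[tuple[str, float]]      # (smiles, predicted affinity), descending
    rejects: list[tuple[str, str]]        # (smiles, reason)


def rank_drugs(
    model: DTAModel,
    candidate_smiles: list[str],
    target_sequence: str,
) -> RankingResult:
    """Rank candidate molecules by predicted affinity against one target.

    Unparseable candidates are collected in ``rejects`` rather than
    silently dropped; ties keep input order.
    """
    enc = featurize.encode_protein(target_sequence)
    graphs, kept, rejects = [], [], []
    for smi in candidate_smiles:
        try:
            graphs.append(featurize.smiles_to_graph(smi))
            kept.append(smi)
        except featurize.SmilesParseError as err:
            rejects.append((smi, str(err)))
    if not kept:
        return RankingResult(ranking=[], rejects=rejects)
    scores = model.predict_pairs(graphs, [enc] * len(kept))
    order = sorted(range(len(kept)), key=lambda i: (-scores[i], i))
    return RankingResult(
        ranking=[(kept[i], float(scores[i])) for i in order],
        rejects=rejects,
    )
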