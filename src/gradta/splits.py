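"""Seeded dataset partitioning: random, k-fold, and cold-start splits.

Cold-start scenarios evaluate generalisation to unseen chemistry/biology:
``cold_drug`` keeps every drug in exactly one of train/validation/test (so
test drugs were never trained on), ``cold_target`` does the same for
proteins, and ``cold_pair`` partitions both entity sets and keeps only
pairs whose drug and target fall in the same partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import AffinityDataset

SCENARIOS = ("random", "kfold", "cold_drug", "cold_target", "cold_pair")


@dataclass(frozen=True)
class Split:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    scenario: str
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("train", "validation", "test"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64)
            )
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/validation/test index sets overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "seed": self.seed,
                "train": self.train.tolist(),
                "validation": self.validation.tolist(),
                "test": self.test.tolist(),
                "meta": self.meta,
            }
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "Split":
        obj = json.loads(text)
        return cls(
            train=obj["train"],
            validation=obj["validation"],
            test=obj["test"],
            scenario=obj["scenario"],
            seed=obj["seed"],
            meta=obj.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "Split":
        return cls.from_json(Path(path).read_text())


def _partition_sizes(n: int, ratios) -> list[int]:
    """Largest-remainder allocation of n items into len(ratios) parts."""
    ratios = np.asarray(ratios, dtype=float)
    exact = n * ratios / ratios.sum()
    sizes = np.floor(exact).astype(int)
    remainder = n - sizes.sum()
    # distribute leftovers to the largest fractional parts (stable order)
    order = np.argsort(-(exact - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes.tolist()


def random_split(ds: AffinityDataset, ratio=(5, 1), seed: int = 0) -> Split:
    """Uniform shuffle into train/test with sizes proportional to ``ratio``."""
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if min(ratio) <= 0:
        raise ValueError("ratio entries must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ds))
    n_train, n_test = _partition_sizes(len(ds), ratio)
    return Split(
        train=np.sort(perm[:n_train]),
        validation=np.array([], dtype=np.int64),
        test=np.sort(perm[n_train:]),
        scenario="random",
        seed=seed,
    )


def kfold_split(ds: AffinityDataset, k: int = 5, seed: int = 0) -> list[Split]:
    """k splits whose validation folds partition the dataset; sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(ds) < k:
        raise ValueError(f"dataset of size {len(ds)} cannot be split into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ds))
    folds = np.array_split(perm, k)
    splits = []
    for i, fold in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        splits.append(
            Split(
                train=np.sort(train),
                validation=np.sort(fold),
                test=np.array([], dtype=np.int64),
                scenario="kfold",
                seed=seed,
                meta={"fold": i, "k": k},
            )
        )
    return splits


def _partition_entities(entities: list[str], ratios, rng) -> dict[str, int]:
    """Assign each entity to partition 0 (train) / 1 (validation) / 2 (test)."""
    entities = list(entities)
    perm = rng.permutation(len(entities))
    sizes = _partition_sizes(len(entities), ratios)
    assignment: dict[str, int] = {}
    start = 0
    for part, size in enumerate(sizes):
        for idx in perm[start : start + size]:
            assignment[entities[idx]] = part
        start += size
    return assignment


def cold_split(
    ds: AffinityDataset,
    scenario: str,
    ratios=(8, 1, 1),
    seed: int = 0,
) -> Split:
    """Entity-level 8:1:1 split for the three cold-start scenarios.

    The ratio applies to the constrained entity sets (drugs and/or
    targets); pair counts then follow the entities.  In ``cold_pair`` both
    entity sets are partitioned independently and pairs whose drug and
    target land in different partitions are discarded (their discarded
    fraction is recorded in ``meta``).
    """
    if scenario not in ("cold_drug", "cold_target", "cold_pair"):
        raise ValueError(f"unknown cold-start scenario: {scenario!r}")
    rng = np.random.default_rng(seed)
    used_drugs = sorted({r.drug_id for r in ds.records})
    used_targets = sorted({r.target_id for r in ds.records})
    n_parts = len(ratios)
    if scenario in ("cold_drug", "cold_pair") and len(used_drugs) < n_parts:
        raise ValueError(f"{scenario}: needs at least {n_parts} unique drugs")
    if scenario in ("cold_target", "cold_pair") and len(used_targets) < n_parts:
        raise ValueError(f"{scenario}: needs at least {n_parts} unique targets")

    drug_part = (
        _partition_entities(used_drugs, ratios, rng)
        if scenario in ("cold_drug", "cold_pair")
        else None
    )
    target_part = (
        _partition_entities(used_targets, ratios, rng)
        if scenario in ("cold_target", "cold_pair")
        else None
    )

    buckets: list[list[int]] = [[] for _ in range(n_parts)]
    dropped = 0
    for i, rec in enumerate(ds.records):
        if scenario == "cold_drug":
            part = drug_part[rec.drug_id]
        elif scenario == "cold_target":
            part = target_part[rec.target_id]
        else:
            dp, tp = drug_part[rec.drug_id], target_part[rec.target_id]
            if dp != tp:
                dropped += 1
                continue
            part = dp
        buckets[part].append(i)

    meta: dict = {"ratios": list(ratios)}
    if scenario == "cold_pair":
        meta["dropped_pairs"] = dropped
        meta["dropped_fraction"] = dropped / max(len(ds), 1)
    return Split(
        train=np.array(buckets[0], dtype=np.int64),
        validation=np.array(buckets[1], dtype=np.int64),
        test=np.array(buckets[2], dtype=np.int64),
        scenario=scenario,
        seed=seed,
        meta=meta,
    )
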