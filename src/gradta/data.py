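"""Affinity datasets: (drug id, target id, affinity) records plus lookup tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from . import featurize


class AffinityRecord(NamedTuple):
    drug_id: str
    target_id: str
    affinity: float


@dataclass
class AffinityDataset:
    """Drug/target lookup tables plus a list of affinity records.

    ``drugs`` maps drug id -> SMILES, ``targets`` maps target id -> amino
    acid sequence; every record references ids present in those tables.
    """

    drugs: dict[str, str]
    targets: dict[str, str]
    records: list[AffinityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.drug_id not in self.drugs:
                raise KeyError(f"record references unknown drug id {rec.drug_id!r}")
            if rec.target_id not in self.targets:
                raise KeyError(f"record references unknown target id {rec.target_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AffinityRecord]:
        return iter(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records], dtype=float)

    def drug_ids(self) -> list[str]:
        return [r.drug_id for r in self.records]

    def target_ids(self) -> list[str]:
        return [r.target_id for r in self.records]

    def subset(self, indices) -> "AffinityDataset":
        recs = [self.records[i] for i in indices]
        return AffinityDataset(drugs=self.drugs, targets=self.targets, records=recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["drug_id", "target_id", "affinity"])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        drugs: dict[str, str],
        targets: dict[str, str],
    ) -> "AffinityDataset":
        recs = [
            AffinityRecord(str(r.drug_id), str(r.target_id), float(r.affinity))
            for r in frame.itertuples(index=False)
        ]
        return cls(drugs=drugs, targets=targets, records=recs)

    def save(self, directory) -> None:
        """Write drugs.csv (id, smiles), targets.fasta and affinities.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"drug_id": list(self.drugs), "smiles": list(self.drugs.values())}
        ).to_csv(directory / "drugs.csv", index=False)
        featurize.write_fasta(directory / "targets.fasta", self.targets)
        self.to_frame().to_csv(directory / "affinities.csv", index=False)

    @classmethod
    def load(cls, directory) -> "AffinityDataset":
        directory = Path(directory)
        drug_frame = pd.read_csv(directory / "drugs.csv", dtype=str)
        drugs = dict(zip(drug_frame["drug_id"], drug_frame["smiles"]))
        targets = featurize.read_fasta(directory / "targets.fasta")
        frame = pd.read_csv(directory / "affinities.csv")
        return cls.from_frame(frame, drugs=drugs, targets=targets)
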