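"""Affinity-scale transforms.

Binding strengths are reported in heterogeneous units: dissociation
constants (K_d), inhibition constants (K_i) and half-maximal inhibitory
concentrations (IC50), all in nM here.  Two standard transforms put them on
modelling-friendly scales: the negative log-molar transform pK_d, and the
KIBA score, which harmonises K_i, K_d and IC50 into a single value using
two fixed weights L_i and L_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RawAffinity:
    """Raw measured affinities in nM; at least one field must be present."""

    kd: float | None = None
    ki: float | None = None
    ic50: float | None = None

    def __post_init__(self) -> None:
        vals = [v for v in (self.kd, self.ki, self.ic50) if v is not None]
        if not vals:
            raise ValueError("at least one of kd, ki, ic50 must be present")
        if any(v <= 0 for v in vals):
            raise ValueError("affinity values must be positive")


def pkd_from_kd(kd: float) -> float:
    """pK_d = -log10(K_d / 1e9) for K_d in nM.

    K_d = 10,000 nM (the floor used when no binding is detected in kinase
    panels) maps to pK_d = 5.0; K_d = 1 nM maps to 9.0.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    return -math.log10(kd / 1e9)


def kiba_score(raw: RawAffinity, l_i: float, l_d: float) -> float:
    """Combine K_i, K_d and IC50 into a KIBA score.

    K_i' = IC50 / (1 + L_i * IC50/K_i) and K_d' = IC50 / (1 + L_d * IC50/K_d)
    are adjusted affinities; the score is K_i' when only (IC50, K_i) are
    available, K_d' when only (IC50, K_d) are available, and their mean when
    all three measurements are present.  IC50 is required in every case.

    L_i and L_d are dataset-calibration weights with no universal default;
    they must be supplied by the caller.
    """
    if raw.ic50 is None:
        raise ValueError("kiba_score requires an IC50 measurement")
    if not (math.isfinite(l_i) and math.isfinite(l_d)):
        raise ValueError("weights l_i and l_d must be finite")
    ki_adj = (
        raw.ic50 / (1.0 + l_i * (raw.ic50 / raw.ki)) if raw.ki is not None else None
    )
    kd_adj = (
        raw.ic50 / (1.0 + l_d * (raw.ic50 / raw.kd)) if raw.kd is not None else None
    )
    if ki_adj is not None and kd_adj is not None:
        return 0.5 * (ki_adj + kd_adj)
    if ki_adj is not None:
        return ki_adj
    if kd_adj is not None:
        return kd_adj
    raise ValueError("kiba_score requires K_i and/or K_d alongside IC50")
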