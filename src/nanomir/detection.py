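"""LOD-based detection calls and the >50% prevalence filter.

A probe is *detected* in a lane when its normalized count lies strictly
above that lane's limit of detection (computed from the lane's own raw
negative controls).  Downstream analysis keeps only endogenous miRNAs
detected in more than half of the lanes under consideration — by default
the union of the contrast's tumor and control lanes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .qc import NormalizedMatrix


@dataclass
class DetectionMatrix:
    """Boolean probes x lanes detection table plus the LODs that produced it."""

    detected: pd.DataFrame
    lods: pd.Series
    probes: pd.DataFrame

    @property
    def lanes(self) -> list[str]:
        return list(self.detected.columns)

    @property
    def endogenous_names(self) -> list[str]:
        return list(self.probes.index[self.probes["code_class"] == "Endogenous"])


@dataclass
class DetectionSummary:
    """Detection prevalence counts over endogenous miRNAs."""

    n_detected_any: int
    n_detected_majority: int
    n_detected_all: int

    def to_dict(self) -> dict:
        return {
            "any": self.n_detected_any,
            "majority": self.n_detected_majority,
            "all": self.n_detected_all,
        }


def detect(norm: NormalizedMatrix, lods: pd.Series) -> DetectionMatrix:
    """Call detection per cell: normalized count strictly above the lane LOD."""
    missing = [l for l in norm.lanes if l not in lods.index]
    if missing:
        raise ConfigurationError(f"no LOD provided for lanes: {missing}")
    detected = norm.counts.gt(lods.reindex(norm.counts.columns), axis=1)
    return DetectionMatrix(detected=detected, lods=lods.reindex(norm.counts.columns), probes=norm.probes)


def _subset(det: DetectionMatrix, lane_subset: Sequence[str]) -> pd.DataFrame:
    lanes = list(lane_subset)
    if not lanes:
        raise ValidationError("lane subset must be non-empty")
    missing = [l for l in lanes if l not in det.detected.columns]
    if missing:
        raise ValidationError(f"unknown lanes in subset: {missing}")
    return det.detected.loc[det.endogenous_names, lanes]


def prevalence_filter(
    det: DetectionMatrix, lane_subset: Sequence[str], fraction: float = 0.5
) -> list[str]:
    """Endogenous probes detected in strictly more than ``fraction`` of lanes.

    The boundary is strict: with 14 lanes and the default 0.5, a probe
    detected in exactly 7 lanes is excluded and one detected in 8 retained.
    """
    sub = _subset(det, lane_subset)
    frac = sub.sum(axis=1) / sub.shape[1]
    return list(sub.index[frac > fraction])


def summarize(det: DetectionMatrix, lane_subset: Sequence[str]) -> DetectionSummary:
    """Count endogenous miRNAs detected in >=1, >50%, and all lanes."""
    sub = _subset(det, lane_subset)
    n = sub.shape[1]
    per_probe = sub.sum(axis=1)
    return DetectionSummary(
        n_detected_any=int((per_probe >= 1).sum()),
        n_detected_majority=int((per_probe / n > 0.5).sum()),
        n_detected_all=int((per_probe == n).sum()),
    )
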