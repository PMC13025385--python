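"""Lane-level quality control and dual-stage geometric-mean normalization.

The nCounter convention equalizes control-probe geometric means across lanes
in two multiplicative stages:

1. **Positive-control normalization** — per lane, the geometric mean of the
   six synthetic spike-ins; the lane factor is the cohort's arithmetic mean
   of those geometric means divided by the lane's own.  Factors outside
   [0.3, 3.0] are flagged.
2. **Content normalization** — the same construction over the five mRNA
   reference genes (ACTB, B2M, GAPDH, RPL19, RPLP0), correcting RNA input
   and quality; factors outside [0.1, 10.0] are flagged.

Background is summarized per lane by a limit of detection (LOD): the mean of
the eight negative-control counts plus ``k`` sample standard deviations
(k = 2 by default).  Further lane checks: the 0.5 fM POS_E spike-in must
exceed every negative control; the three positive ligation controls must all
exceed the LOD and increase from LIG_POS_C to LIG_POS_A while the three
negative ligation controls stay below it; and the positive titration must be
log-log linear (R^2 >= 0.95 expected; a miss is a warning, never an
exclusion).  Flagged lanes are retained and recorded, not excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientControlsError, QCError
from .rcc import (
    CountMatrix,
    LaneRecord,
    REFERENCE_GENES,
    positive_concentration,
)

logger = logging.getLogger(__name__)

#: Acceptable range for positive-control normalization factors (closed).
POS_FLAG_RANGE = (0.3, 3.0)
#: Acceptable range for content normalization factors (closed).
CONTENT_FLAG_RANGE = (0.1, 10.0)
#: R^2 below which the positive titration draws a linearity warning.
LINEARITY_R2_WARN = 0.95


def compute_lod(negative_counts: Iterable[float], k: float = 2.0) -> float:
    """Limit of detection: mean of negative controls plus ``k`` sample SDs.

    The standard deviation uses the n-1 denominator (small control panels).
    """
    neg = np.asarray(list(negative_counts), dtype=float)
    if neg.size < 2:
        raise InsufficientControlsError(
            f"LOD needs at least 2 negative-control counts, got {neg.size}"
        )
    return float(neg.mean() + k * neg.std(ddof=1))


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean with the digital-count zero guard.

    Zero counts are replaced by 1 (the smallest observable signal) with a
    warning before taking exp(mean(log)).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    if np.any(vals < 0):
        raise ValueError("geometric mean requires non-negative counts")
    n_zero = int((vals == 0).sum())
    if n_zero:
        logger.warning("replacing %d zero count(s) by 1 before geometric mean", n_zero)
        vals = np.where(vals == 0, 1.0, vals)
    return float(np.exp(np.log(vals).mean()))


def _lane_geomeans(matrix: CountMatrix, probe_names: Sequence[str]) -> pd.Series:
    sub = matrix.counts.loc[list(probe_names)]
    return pd.Series(
        {lane: geometric_mean(sub[lane].to_numpy()) for lane in matrix.lanes},
        name="geomean",
    )


def positive_norm_factors(matrix: CountMatrix) -> pd.Series:
    """Per-lane positive-control normalization factors.

    factor(lane) = mean over lanes of positive geometric means, divided by
    that lane's positive geometric mean — so identical lanes get exactly 1.
    """
    pos_names = matrix.names_of_class("Positive")
    if not pos_names:
        raise InsufficientControlsError("no Positive-class probes in the matrix")
    for lane in matrix.lanes:
        if (matrix.counts.loc[pos_names, lane] == 0).all():
            raise QCError(
                f"lane {lane!r}: all positive-control counts are zero (QC-fatal)"
            )
    geo = _lane_geomeans(matrix, pos_names)
    factors = geo.mean() / geo
    factors.name = "pos_factor"
    return factors


def content_norm_factors(
    matrix, reference_genes: Sequence[str] = REFERENCE_GENES
) -> pd.Series:
    """Per-lane content normalization factors over the mRNA reference genes.

    Accepts a raw or an already positive-normalized matrix; in the dual-stage
    architecture the content factors are estimated on the positive-normalized
    counts (see :func:`dual_normalize`), otherwise the technical lane scale
    would be corrected twice.
    """
    missing = [g for g in reference_genes if g not in matrix.counts.index]
    if missing:
        raise ConfigurationError(f"reference gene(s) missing from panel: {missing}")
    geo = _lane_geomeans(matrix, list(reference_genes))
    factors = geo.mean() / geo
    factors.name = "content_factor"
    return factors


def factor_flags(factors: pd.Series, low: float, high: float) -> pd.Series:
    """Flag factors strictly outside the closed interval [low, high]."""
    return (factors < low) | (factors > high)


@dataclass
class NormalizedMatrix:
    """Real-valued counts after one or both normalization stages."""

    probes: pd.DataFrame
    counts: pd.DataFrame
    design: dict[str, str]
    provenance: tuple[str, ...] = ()

    @property
    def lanes(self) -> list[str]:
        return list(self.counts.columns)

    def names_of_class(self, code_class: str) -> list[str]:
        return list(self.probes.index[self.probes["code_class"] == code_class])

    @property
    def endogenous_names(self) -> list[str]:
        return self.names_of_class("Endogenous")

    def lanes_in_group(self, group: str) -> list[str]:
        return [l for l in self.lanes if self.design[l] == group]


def apply_normalization(
    matrix: CountMatrix,
    pos_factors: Optional[pd.Series] = None,
    content_factors: Optional[pd.Series] = None,
) -> NormalizedMatrix:
    """Multiply each lane by its positive-stage then content-stage factor.

    Either stage may be omitted (pass ``None``) to inspect intermediate
    matrices; after the positive stage alone the per-lane geometric means of
    the spike-ins agree across lanes to floating-point precision.
    """
    counts = matrix.counts.astype(float).copy()
    provenance: list[str] = []
    for stage, factors in (("positive", pos_factors), ("content", content_factors)):
        if factors is None:
            continue
        missing = [l for l in matrix.lanes if l not in factors.index]
        if missing:
            raise ConfigurationError(f"{stage} factors missing for lanes: {missing}")
        counts = counts * factors.reindex(counts.columns)
        provenance.append(stage)
    return NormalizedMatrix(
        probes=matrix.probes,
        counts=counts,
        design=dict(matrix.design),
        provenance=tuple(provenance),
    )


def dual_normalize(
    matrix: CountMatrix, reference_genes: Sequence[str] = REFERENCE_GENES
) -> tuple[NormalizedMatrix, pd.Series, pd.Series]:
    """The dual-stage architecture: positive stage first, content stage after.

    Positive factors come from the raw spike-in counts; content factors are
    then estimated on the positive-normalized matrix, so each stage corrects
    only the variation the previous one left behind.  Returns the fully
    normalized matrix with both factor sets.
    """
    pos = positive_norm_factors(matrix)
    stage1 = apply_normalization(matrix, pos_factors=pos)
    content = content_norm_factors(stage1, reference_genes)
    return apply_normalization(matrix, pos, content), pos, content


def lane_lods(matrix: CountMatrix, k: float = 2.0) -> pd.Series:
    """Per-lane LOD from that lane's own raw negative-control counts."""
    neg_names = matrix.names_of_class("Negative")
    lods = pd.Series(
        {
            lane: compute_lod(matrix.counts.loc[neg_names, lane].to_numpy(), k=k)
            for lane in matrix.lanes
        },
        name="lod",
    )
    return lods


@dataclass
class LaneQC:
    """All QC verdicts for one lane."""

    lane_id: str
    lod: float
    pos_factor: float
    content_factor: float
    pos_factor_flagged: bool
    content_factor_flagged: bool
    pose_above_background: bool
    ligation_pass: bool
    pos_linearity_r2: float

    @property
    def linearity_warning(self) -> bool:
        return self.pos_linearity_r2 < LINEARITY_R2_WARN

    def to_dict(self) -> dict:
        d = {
            "lane_id": self.lane_id,
            "lod": self.lod,
            "pos_factor": self.pos_factor,
            "content_factor": self.content_factor,
            "pos_factor_flagged": self.pos_factor_flagged,
            "content_factor_flagged": self.content_factor_flagged,
            "pose_above_background": self.pose_above_background,
            "ligation_pass": self.ligation_pass,
            "pos_linearity_r2": self.pos_linearity_r2,
            "linearity_warning": self.linearity_warning,
        }
        return d


def _control_rules(
    counts: Mapping[str, float],
    classes: Mapping[str, str],
    lod: float,
) -> tuple[bool, bool, float]:
    """POS_E, ligation-order, and titration-linearity rules for one lane."""
    negatives = [counts[n] for n, c in classes.items() if c == "Negative"]
    if len(negatives) < 2:
        raise QCError("lane QC needs at least 2 negative-control probes")

    pos_e = [
        n
        for n, c in classes.items()
        if c == "Positive" and positive_concentration(n) == 0.5
    ]
    if not pos_e:
        raise QCError("missing control probe POS_E (0.5 fM spike-in)")
    pose_above_background = counts[pos_e[0]] > max(negatives)

    lig = {n.upper(): counts[n] for n, c in classes.items() if c == "Ligation"}
    lig_pos = {s: lig.get(f"LIG_POS_{s}") for s in "ABC"}
    lig_neg = [v for k, v in lig.items() if k.startswith("LIG_NEG")]
    missing = [f"LIG_POS_{s}" for s, v in lig_pos.items() if v is None]
    if missing or len(lig_neg) != 3:
        raise QCError(f"missing ligation control probe(s): {missing or 'LIG_NEG_*'}")
    ligation_pass = (
        all(v > lod for v in lig_pos.values())
        and lig_pos["C"] < lig_pos["B"] < lig_pos["A"]
        and all(v < lod for v in lig_neg)
    )

    pos = [
        (positive_concentration(n), counts[n])
        for n, c in classes.items()
        if c == "Positive" and positive_concentration(n) is not None
    ]
    if len(pos) < 3:
        raise QCError("positive titration needs at least 3 annotated spike-ins")
    conc = np.log2([c for c, _ in pos])
    sig = np.log2(np.asarray([v for _, v in pos], dtype=float) + 1.0)
    if np.allclose(sig, sig[0]):
        r2 = 0.0  # flat signal carries no titration information
    else:
        r = stats.pearsonr(conc, sig).statistic
        r2 = float(r**2)
    return pose_above_background, ligation_pass, r2


def lane_qc(
    lane: LaneRecord,
    lod: float,
    pos_factor: float = math.nan,
    content_factor: float = math.nan,
) -> LaneQC:
    """Evaluate the per-lane control rules against a given LOD.

    Normalization factors are cohort-level quantities; pass them in when
    known (see :func:`cohort_qc`), otherwise they are recorded as NaN and
    unflagged.
    """
    counts = {p.name: float(p.count) for p in lane.probes}
    classes = {p.name: p.code_class for p in lane.probes}
    pose_ok, lig_ok, r2 = _control_rules(counts, classes, lod)
    return LaneQC(
        lane_id=lane.lane_id,
        lod=lod,
        pos_factor=pos_factor,
        content_factor=content_factor,
        pos_factor_flagged=bool(
            not math.isnan(pos_factor)
            and factor_flags(pd.Series([pos_factor]), *POS_FLAG_RANGE).iloc[0]
        ),
        content_factor_flagged=bool(
            not math.isnan(content_factor)
            and factor_flags(pd.Series([content_factor]), *CONTENT_FLAG_RANGE).iloc[0]
        ),
        pose_above_background=pose_ok,
        ligation_pass=lig_ok,
        pos_linearity_r2=r2,
    )


def cohort_qc(matrix: CountMatrix, k: float = 2.0) -> list[LaneQC]:
    """Full QC for every lane of a cohort: LODs, both factor sets, and rules."""
    lods = lane_lods(matrix, k=k)
    _, pos_factors, content_factors = dual_normalize(matrix)
    pos_flags = factor_flags(pos_factors, *POS_FLAG_RANGE)
    content_flags = factor_flags(content_factors, *CONTENT_FLAG_RANGE)
    classes = matrix.probes["code_class"].to_dict()
    out: list[LaneQC] = []
    for lane in matrix.lanes:
        counts = matrix.counts[lane].astype(float).to_dict()
        pose_ok, lig_ok, r2 = _control_rules(counts, classes, float(lods[lane]))
        out.append(
            LaneQC(
                lane_id=lane,
                lod=float(lods[lane]),
                pos_factor=float(pos_factors[lane]),
                content_factor=float(content_factors[lane]),
                pos_factor_flagged=bool(pos_flags[lane]),
                content_factor_flagged=bool(content_flags[lane]),
                pose_above_background=pose_ok,
                ligation_pass=lig_ok,
                pos_linearity_r2=r2,
            )
        )
    return out


def qc_table(qcs: Sequence[LaneQC]) -> pd.DataFrame:
    """One row per lane, suitable for the TSV QC report."""
    return pd.DataFrame([q.to_dict() for q in qcs]).set_index("lane_id")
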