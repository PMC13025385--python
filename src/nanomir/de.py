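"""Signed fold-change differential expression and cross-contrast intersection.

Group means are arithmetic means of normalized counts.  The fold change is
reported in the signed nSolver convention: the case/control ratio when it is
at least 1, and the negative reciprocal otherwise, so -2 means halved and no
value ever lies strictly between -1 and 1.  Selection uses the fold-change
magnitude alone (|FC| > 2 by default, strict); a two-sided Welch t-test on
log2(count+1) with Benjamini-Hochberg adjustment is reported alongside for
context but never drives the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

#: Default fold-change magnitude cutoff for a significant call (strict).
FC_THRESHOLD = 2.0

#: Floor applied to group means (smallest observable digital count) so the
#: ratio is defined even for probes with an all-zero group.
MEAN_FLOOR = 1.0


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Case/control ratio if >= 1, else the negative reciprocal.

    Both means must be strictly positive (upstream flooring guarantees it).
    """
    if mean_case <= 0 or mean_control <= 0:
        raise ValidationError(
            f"signed fold change needs positive means, got case={mean_case}, "
            f"control={mean_control}"
        )
    r = mean_case / mean_control
    return float(r) if r >= 1.0 else float(-1.0 / r)


@dataclass
class Contrast:
    """A case-vs-control comparison over a prevalence-filtered probe list."""

    case_group: str
    control_group: str
    fc_threshold: float = FC_THRESHOLD
    retained_probes: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        if self.case_group == self.control_group:
            raise ValidationError("contrast groups must be distinct")


#: Column order of a differential-expression table.
DE_COLUMNS = (
    "mirna",
    "mean_case",
    "mean_control",
    "fold_change",
    "p_value",
    "p_adjusted",
    "significant",
)


def de_table(norm: NormalizedMatrix, contrast: Contrast) -> pd.DataFrame:
    """One row per retained probe, sorted by fold change descending.

    Raises when a group has fewer than 2 lanes or the retained probe list is
    empty.
    """
    retained = list(contrast.retained_probes)
    if not retained:
        raise ValidationError("contrast has no retained probes")
    case_lanes = norm.lanes_in_group(contrast.case_group)
    ctrl_lanes = norm.lanes_in_group(contrast.control_group)
    for label, lanes in ((contrast.case_group, case_lanes), (contrast.control_group, ctrl_lanes)):
        if len(lanes) < 2:
            raise ValidationError(f"group {label!r} has {len(lanes)} lane(s); need >=2")

    case = norm.counts.loc[retained, case_lanes].to_numpy(dtype=float)
    ctrl = norm.counts.loc[retained, ctrl_lanes].to_numpy(dtype=float)

    mean_case = np.maximum(case.mean(axis=1), MEAN_FLOOR)
    mean_control = np.maximum(ctrl.mean(axis=1), MEAN_FLOOR)
    fc = np.array(
        [signed_fold_change(a, b) for a, b in zip(mean_case, mean_control)]
    )

    t = stats.ttest_ind(np.log2(case + 1.0), np.log2(ctrl + 1.0), axis=1, equal_var=False)
    p = np.asarray(t.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance degenerate cells
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mirna": retained,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fold_change": fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": np.abs(fc) > contrast.fc_threshold,
        }
    )
    table = table.sort_values(
        ["fold_change", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table[list(DE_COLUMNS)]


def overexpressed_set(table: pd.DataFrame) -> set[str]:
    """Probes called significant with a positive fold change."""
    mask = table["significant"] & (table["fold_change"] > 0)
    return set(table.loc[mask, "mirna"])


def overexpressed_intersection(tables: Iterable[pd.DataFrame]) -> set[str]:
    """Probes overexpressed (significant, FC > 0) in every contrast."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValidationError("intersection needs at least 2 DE tables")
    result = overexpressed_set(tables[0])
    for t in tables[1:]:
        result &= overexpressed_set(t)
    return result
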