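"""Offline annotation of DE miRNAs with validated target genes.

Live miRNA-target databases (miRTarBase, miRDB, miRTargetLink) return
version-dependent answers, so the pipeline works exclusively from a local
TSV of interactions with an ``evidence`` tag (``validated`` from reporter
assays and curated sources, ``predicted`` otherwise).  A small curated table
covering the melanoma-relevant interactions of miR-146a-5p and miR-4286 —
including their shared target WASF2 — ships with the package as the default.

miRNA name matching is case-insensitive with any ``hsa-`` species prefix
stripped, since panel and database naming conventions differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

EVIDENCE_LEVELS = ("validated", "predicted")

_REQUIRED_COLUMNS = ("mirna", "gene", "evidence")


def normalize_mirna(name: str) -> str:
    """Canonical matching key: lowercase, ``hsa-`` prefix removed."""
    key = name.strip().lower()
    if key.startswith("hsa-"):
        key = key[4:]
    return key


@dataclass
class TargetTable:
    """Curated miRNA-target interactions indexed by matching key."""

    interactions: pd.DataFrame  # columns: mirna, gene, evidence, source_note, _key

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def mirnas(self) -> set[str]:
        return set(self.interactions["mirna"])


def load_targets(path=None) -> TargetTable:
    """Load a target table from TSV; defaults to the packaged curated table.

    Requires columns ``mirna``, ``gene``, ``evidence``; duplicate
    (mirna, gene) pairs are collapsed with a warning; evidence values
    outside the closed vocabulary raise :class:`ValidationError`.
    """
    if path is None:
        with resources.as_file(
            resources.files("nanomir").joinpath("data/validated_targets.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"target table missing column(s): {missing}")
    if "source_note" not in df.columns:
        df["source_note"] = ""
    df = df.fillna({"source_note": ""})

    bad = sorted(set(df["evidence"]) - set(EVIDENCE_LEVELS))
    if bad:
        raise ValidationError(
            f"unknown evidence value(s) {bad}; expected one of {EVIDENCE_LEVELS}"
        )

    df["_key"] = df["mirna"].map(normalize_mirna)
    n_before = len(df)
    df = df.drop_duplicates(subset=["_key", "gene"], keep="first").reset_index(drop=True)
    if len(df) < n_before:
        logger.warning(
            "collapsed %d duplicate miRNA-target pair(s)", n_before - len(df)
        )
    return TargetTable(interactions=df)


def targets_of(
    table: TargetTable, mirna: str, evidence_filter: Optional[str] = None
) -> set[str]:
    """Target genes of one miRNA, optionally restricted by evidence level.

    Unknown miRNAs yield an empty set.
    """
    if evidence_filter is not None and evidence_filter not in EVIDENCE_LEVELS:
        raise ValidationError(f"unknown evidence filter {evidence_filter!r}")
    df = table.interactions
    mask = df["_key"] == normalize_mirna(mirna)
    if evidence_filter is not None:
        mask &= df["evidence"] == evidence_filter
    return set(df.loc[mask, "gene"])


def shared_targets(
    table: TargetTable, mirnas: Iterable[str], evidence_filter: Optional[str] = None
) -> set[str]:
    """Genes targeted by every listed miRNA (at least two required)."""
    mirnas = list(mirnas)
    if len(mirnas) < 2:
        raise ValidationError("shared_targets needs at least 2 miRNAs")
    result = targets_of(table, mirnas[0], evidence_filter)
    for m in mirnas[1:]:
        result &= targets_of(table, m, evidence_filter)
    return result


def annotate_de(
    results: pd.DataFrame, table: TargetTable, evidence_filter: str = "validated"
) -> pd.DataFrame:
    """Attach each significant miRNA's target list to a DE table.

    Returns a copy with a ``validated_targets`` column (semicolon-joined,
    alphabetical); non-significant rows get an empty string.  No numeric DE
    field is modified.
    """
    out = results.copy()
    annot = []
    for _, row in out.iterrows():
        if bool(row["significant"]):
            genes = sorted(targets_of(table, row["mirna"], evidence_filter))
            annot.append(";".join(genes))
        else:
            annot.append("")
    out["validated_targets"] = annot
    return out


def edge_list(table: TargetTable, mirnas: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """miRNA-gene edge list for export to graph tools."""
    df = table.interactions
    if mirnas is not None:
        keys = {normalize_mirna(m) for m in mirnas}
        df = df[df["_key"].isin(keys)]
    return df[["mirna", "gene", "evidence"]].reset_index(drop=True)
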