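"""Reading and writing RCC lane files and assembling count matrices.

An RCC file is the per-lane text output of the nCounter instrument: a series
of bracket-delimited sections (``<Header>`` ... ``</Header>``) holding
``key,value`` lines, plus a ``Code_Summary`` section with one
``CodeClass,Name,Accession,Count`` row per probe.  One file corresponds to
one cartridge lane, i.e. one sample.

The probe panel mixes five code classes:

* ``Endogenous`` — the assayed miRNAs,
* ``Positive`` — six synthetic spike-ins at a titration from 128 down to
  0.125 fM (POS_A..POS_F; POS_E, at 0.5 fM, marks the system detection limit),
* ``Negative`` — eight probes with no target, defining background,
* ``Ligation`` — six constructs probing the miRNA tag-ligation chemistry
  (three positives LIG_POS_A/B/C that must ligate, three negatives that
  must not),
* ``Housekeeping`` — five mRNA reference genes (ACTB, B2M, GAPDH, RPL19,
  RPLP0) used for content normalization.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    DesignError,
    IncompatibleLanesError,
    RCCFormatError,
    RCCParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical code-class vocabulary.
CODE_CLASSES = ("Endogenous", "Positive", "Negative", "Ligation", "Housekeeping")

#: Panel-version synonyms mapped onto the canonical vocabulary.
_CLASS_SYNONYMS = {
    "reference": "Housekeeping",
    "housekeeping": "Housekeeping",
    "spikein": "Positive",
    "positive": "Positive",
    "negative": "Negative",
    "ligation": "Ligation",
    "endogenous": "Endogenous",
}

#: Nominal spike-in concentrations (fM) for the positive-control titration.
POSITIVE_CONCENTRATIONS_FM = {
    "A": 128.0,
    "B": 32.0,
    "C": 8.0,
    "D": 2.0,
    "E": 0.5,
    "F": 0.125,
}

#: The five pre-validated mRNA reference genes of the miRNA panel.
REFERENCE_GENES = ("ACTB", "B2M", "GAPDH", "RPL19", "RPLP0")

_POS_NAME_RE = re.compile(r"^POS_([A-F])(?:\(([\d.]+)\))?$", re.IGNORECASE)
_SECTION_RE = re.compile(r"^<(/?)([A-Za-z_][A-Za-z0-9_]*)>\s*$")


def canonical_code_class(raw: str) -> str:
    """Map a raw CodeClass label onto the canonical vocabulary.

    Unknown labels are returned unchanged; callers keep such probes but
    exclude them from control computations.
    """
    return _CLASS_SYNONYMS.get(raw.strip().lower(), raw.strip())


def positive_concentration(name: str) -> Optional[float]:
    """Nominal fM concentration for a positive-control probe name.

    Accepts both bare (``POS_E``) and annotated (``POS_E(0.5)``) names.
    Returns ``None`` when the name does not follow the POS_A..POS_F
    convention.
    """
    m = _POS_NAME_RE.match(name.strip())
    if m is None:
        return None
    if m.group(2):
        return float(m.group(2))
    return POSITIVE_CONCENTRATIONS_FM.get(m.group(1).upper())


@dataclass(frozen=True)
class ProbeCount:
    """One probe's digital count in one lane."""

    name: str
    code_class: str
    accession: str
    count: int
    nominal_concentration: Optional[float] = None

    def __post_init__(self):
        if self.count < 0 or int(self.count) != self.count:
            raise ValidationError(
                f"probe {self.name!r}: count must be a non-negative integer, "
                f"got {self.count!r}"
            )
        if self.code_class == "Positive" and self.nominal_concentration is not None:
            if self.nominal_concentration <= 0:
                raise ValidationError(
                    f"probe {self.name!r}: nominal concentration must be positive"
                )


@dataclass
class LaneRecord:
    """One lane's raw probe counts plus its instrument metadata.

    ``sample_attributes`` holds the key/value lines of the non-tabular RCC
    sections, namespaced as ``Section.Key`` (e.g. ``Lane_Attributes.ID``) so
    the file can be rewritten section-for-section.
    """

    lane_id: str
    sample_attributes: dict[str, str] = field(default_factory=dict)
    probes: list[ProbeCount] = field(default_factory=list)

    def validate(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"lane {self.lane_id!r}: duplicate probe names {dupes}")
        classes = {p.code_class for p in self.probes}
        if "Negative" not in classes or "Positive" not in classes:
            raise ValidationError(
                f"lane {self.lane_id!r}: must contain at least one Positive and "
                f"one Negative control probe"
            )

    def counts_by_name(self) -> dict[str, int]:
        return {p.name: p.count for p in self.probes}

    def probes_of_class(self, code_class: str) -> list[ProbeCount]:
        return [p for p in self.probes if p.code_class == code_class]


def _parse_sections(text: str, path: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _SECTION_RE.match(line.strip())
        if m:
            closing, name = m.group(1) == "/", m.group(2)
            if closing:
                if name != current:
                    raise RCCFormatError(
                        f"{path}: line {lineno}: unexpected section close </{name}>"
                    )
                current = None
            else:
                current = name
                sections.setdefault(name, [])
            continue
        if current is not None and line.strip():
            sections[current].append(line)
    return sections


def read_rcc(path) -> LaneRecord:
    """Parse one RCC lane file into a :class:`LaneRecord`.

    Unknown sections with ``key,value`` rows are preserved; the free-text
    ``Messages`` section is ignored.  Raises :class:`RCCFormatError` when the
    Code_Summary section is missing, :class:`RCCParseError` on malformed
    rows, and :class:`ValidationError` on duplicate probe names.
    """
    path = Path(path)
    if not path.exists():
        raise RCCFormatError(f"{path}: no such file")
    text = path.read_text()
    sections = _parse_sections(text, str(path))
    if "Code_Summary" not in sections:
        raise RCCFormatError(f"{path}: missing Code_Summary section")

    attrs: dict[str, str] = {}
    for name, lines in sections.items():
        if name in ("Code_Summary", "Messages"):
            continue
        for line in lines:
            parts = next(csv.reader(io.StringIO(line)))
            if len(parts) >= 1:
                key = parts[0].strip()
                value = ",".join(parts[1:]) if len(parts) > 1 else ""
                attrs[f"{name}.{key}"] = value

    probes: list[ProbeCount] = []
    seen: set[str] = set()
    for line in sections["Code_Summary"]:
        parts = next(csv.reader(io.StringIO(line)))
        if [p.strip().lower() for p in parts[:4]] == ["codeclass", "name", "accession", "count"]:
            continue  # header row
        if len(parts) < 4:
            raise RCCParseError(f"{path}: malformed Code_Summary row {line!r}")
        raw_class, name, accession = parts[0].strip(), parts[1].strip(), parts[2].strip()
        try:
            count = int(parts[3].strip())
        except ValueError:
            raise RCCParseError(
                f"{path}: non-integer count in Code_Summary row {line!r}"
            ) from None
        if count < 0:
            raise RCCParseError(f"{path}: negative count in Code_Summary row {line!r}")
        if name in seen:
            raise ValidationError(f"{path}: duplicate probe name {name!r}")
        seen.add(name)
        code_class = canonical_code_class(raw_class)
        conc = positive_concentration(name) if code_class == "Positive" else None
        probes.append(ProbeCount(name, code_class, accession, count, conc))

    unknown = sorted({p.code_class for p in probes} - set(CODE_CLASSES))
    if unknown:
        logger.warning(
            "%s: probes with unrecognised code classes %s are kept but excluded "
            "from control computations",
            path,
            unknown,
        )

    lane_id = (
        attrs.get("Lane_Attributes.ID")
        or attrs.get("Sample_Attributes.ID")
        or path.stem
    )
    return LaneRecord(lane_id=lane_id, sample_attributes=attrs, probes=probes)


def write_rcc(lane: LaneRecord, path) -> None:
    """Write a :class:`LaneRecord` back to RCC format.

    The emitted file re-reads (:func:`read_rcc`) to an equal record.  The
    lane id is injected as ``Lane_Attributes.ID`` if the metadata does not
    already carry one, so identity survives renaming on disk.
    """
    lane.validate()
    attrs = dict(lane.sample_attributes)
    if "Lane_Attributes.ID" not in attrs and "Sample_Attributes.ID" not in attrs:
        attrs["Lane_Attributes.ID"] = lane.lane_id

    by_section: dict[str, list[tuple[str, str]]] = {}
    for key, value in attrs.items():
        section, _, k = key.partition(".")
        by_section.setdefault(section, []).append((k, value))

    out = io.StringIO()
    for section in by_section:
        out.write(f"<{section}>\n")
        for k, v in by_section[section]:
            out.write(f"{k},{v}\n")
        out.write(f"</{section}>\n")
    out.write("<Code_Summary>\n")
    out.write("CodeClass,Name,Accession,Count\n")
    for p in lane.probes:
        out.write(f"{p.code_class},{p.name},{p.accession},{p.count}\n")
    out.write("</Code_Summary>\n")

    Path(path).write_text(out.getvalue())


@dataclass
class CountMatrix:
    """Probes x lanes raw digital counts with class annotations and a design.

    ``probes`` is indexed by probe name with ``code_class`` and ``accession``
    columns; ``counts`` shares that index with one integer column per lane;
    ``design`` maps every lane id to its group label.
    """

    probes: pd.DataFrame
    counts: pd.DataFrame
    design: dict[str, str]

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

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for lane in self.lanes:
            seen.setdefault(self.design[lane], None)
        return list(seen)


def build_matrix(
    lanes: Sequence[LaneRecord], design: Mapping[str, str]
) -> CountMatrix:
    """Assemble lane records sharing one probe set into a :class:`CountMatrix`.

    Probe order is taken from the first lane; lanes whose probe sets differ
    raise :class:`IncompatibleLanesError` naming the symmetric difference,
    and lanes absent from ``design`` raise :class:`DesignError`.
    """
    if len(lanes) < 2:
        raise ValidationError("build_matrix requires at least 2 lanes")
    missing = [l.lane_id for l in lanes if l.lane_id not in design]
    if missing:
        raise DesignError(f"lanes missing from design: {missing}")

    first = lanes[0]
    order = [p.name for p in first.probes]
    ref_set = set(order)
    for lane in lanes[1:]:
        names = {p.name for p in lane.probes}
        if names != ref_set:
            diff = sorted(ref_set.symmetric_difference(names))
            raise IncompatibleLanesError(
                f"lane {lane.lane_id!r} probe set differs from lane "
                f"{first.lane_id!r}; symmetric difference: {diff}"
            )

    probes = pd.DataFrame(
        {
            "code_class": [p.code_class for p in first.probes],
            "accession": [p.accession for p in first.probes],
        },
        index=pd.Index(order, name="name"),
    )
    counts = pd.DataFrame(
        {lane.lane_id: pd.Series(lane.counts_by_name()) for lane in lanes},
        dtype=int,
    ).loc[order]
    counts.index.name = "name"

    unknown = sorted(set(probes["code_class"]) - set(CODE_CLASSES))
    if unknown:
        logger.warning(
            "count matrix contains unrecognised code classes %s; such probes are "
            "excluded from control computations",
            unknown,
        )
    return CountMatrix(probes=probes, counts=counts, design={l: design[l] for l in counts.columns})


def read_design(path) -> dict[str, str]:
    """Read a two-column (lane_id, group) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DesignError(f"{path}: design table needs lane_id and group columns")
    lane_col, group_col = df.columns[:2]
    return dict(zip(df[lane_col], df[group_col]))


def write_design(design: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"lane_id": list(design), "group": [design[l] for l in design]}
    ).to_csv(path, sep="\t", index=False)
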