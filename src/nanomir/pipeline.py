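"""End-to-end orchestration: read -> QC -> normalize -> filter -> DE -> annotate.

Every threshold of the analysis lives in :class:`RunConfig` with the study's
values as defaults, so the zero-configuration run reproduces the published
procedure: LOD = mean(neg) + 2 SD, >50% detection prevalence over the
contrast's tumor-plus-control lanes, |FC| > 2 selection, factor flag ranges
0.3-3.0 (positive stage) and 0.1-10.0 (content stage).  Each run writes its
tables under one output directory along with a manifest recording every
parameter and input checksum; identical inputs and config give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .de import Contrast, de_table, overexpressed_intersection, overexpressed_set
from .detection import detect, prevalence_filter, summarize
from .errors import ConfigurationError, DesignError, PipelineStageError
from .qc import (
    apply_normalization,
    cohort_qc,
    dual_normalize,
    lane_lods,
    qc_table,
)
from .rcc import build_matrix, read_design, read_rcc
from .targets import annotate_de, load_targets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters of one pipeline run."""

    input_dir: Optional[str] = None
    rcc_paths: list[str] = field(default_factory=list)
    design_path: str = ""
    contrasts: list[tuple[str, str]] = field(default_factory=list)  # (case, control)
    k_sd: float = 2.0
    prevalence_fraction: float = 0.5
    prevalence_mode: str = "contrast_union"  # or "case_group"
    detection_source: str = "normalized"  # or "raw"
    fc_threshold: float = 2.0
    pos_flag_range: tuple[float, float] = (0.3, 3.0)
    content_flag_range: tuple[float, float] = (0.1, 10.0)
    target_table_path: Optional[str] = None
    output_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.rcc_paths and not self.input_dir:
            raise ConfigurationError("need input_dir or an explicit rcc_paths list")
        if not self.design_path:
            raise ConfigurationError("design_path is required")
        if not self.contrasts:
            raise ConfigurationError("at least one contrast is required")
        if self.prevalence_mode not in ("contrast_union", "case_group"):
            raise ConfigurationError(
                f"unknown prevalence_mode {self.prevalence_mode!r}"
            )
        if self.detection_source not in ("normalized", "raw"):
            raise ConfigurationError(
                f"unknown detection_source {self.detection_source!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        for key in ("pos_flag_range", "content_flag_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["pos_flag_range"] = list(self.pos_flag_range)
        d["content_flag_range"] = list(self.content_flag_range)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _discover_inputs(config: RunConfig) -> list[Path]:
    if config.rcc_paths:
        return [Path(p) for p in config.rcc_paths]
    paths = sorted(
        p
        for p in Path(config.input_dir).iterdir()
        if p.suffix.lower() == ".rcc"
    )
    if not paths:
        raise ConfigurationError(f"no .rcc files found under {config.input_dir}")
    return paths


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=index)
        outputs.append(name)

    def _write_json(obj, name: str) -> None:
        p = outdir / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True))
        outputs.append(name)

    with _stage("read"):
        paths = _discover_inputs(config)
        lanes = [read_rcc(p) for p in paths]
        design = read_design(config.design_path)
        matrix = build_matrix(lanes, design)
        groups = set(matrix.design.values())
        for case, ctrl in config.contrasts:
            if case not in groups or ctrl not in groups:
                raise DesignError(
                    f"contrast ({case}, {ctrl}) references unknown group labels; "
                    f"design has {sorted(groups)}"
                )

    with _stage("qc"):
        lods = lane_lods(matrix, k=config.k_sd)
        qcs = cohort_qc(matrix, k=config.k_sd)
        qdf = qc_table(qcs)
        _write_tsv(qdf, "lane_qc.tsv")
        _write_json(
            {
                "n_lanes": len(qcs),
                "n_pos_factor_flagged": int(qdf["pos_factor_flagged"].sum()),
                "n_content_factor_flagged": int(qdf["content_factor_flagged"].sum()),
                "all_pose_above_background": bool(qdf["pose_above_background"].all()),
                "all_ligation_pass": bool(qdf["ligation_pass"].all()),
                "min_pos_linearity_r2": float(qdf["pos_linearity_r2"].min()),
            },
            "qc_summary.json",
        )

    with _stage("normalize"):
        norm, pos_factors, content_factors = dual_normalize(matrix)
        _write_tsv(
            pd.DataFrame({"pos_factor": pos_factors, "content_factor": content_factors}),
            "normalization_factors.tsv",
        )
        _write_tsv(norm.counts, "normalized_matrix.tsv")

    with _stage("detect"):
        detection_input = (
            norm if config.detection_source == "normalized"
            else apply_normalization(matrix)  # raw counts, no factor stages
        )
        det = detect(detection_input, lods)
        _write_tsv(
            det.detected.loc[det.endogenous_names].astype(int), "detection_matrix.tsv"
        )

    tables: dict[str, pd.DataFrame] = {}
    detection_summaries: dict[str, dict] = {}
    for case, ctrl in config.contrasts:
        label = f"{case}_vs_{ctrl}"
        with _stage(f"de:{label}"):
            union = matrix.lanes_in_group(case) + matrix.lanes_in_group(ctrl)
            denom = (
                union if config.prevalence_mode == "contrast_union"
                else matrix.lanes_in_group(case)
            )
            detection_summaries[label] = summarize(det, union).to_dict()
            retained = prevalence_filter(det, denom, config.prevalence_fraction)
            contrast = Contrast(
                case_group=case,
                control_group=ctrl,
                fc_threshold=config.fc_threshold,
                retained_probes=retained,
            )
            table = de_table(norm, contrast)
            tables[label] = table
            _write_tsv(table, f"de_{label}.tsv", index=False)
    _write_json(detection_summaries, "detection_summary.json")

    with _stage("intersect"):
        if len(tables) >= 2:
            shared = sorted(overexpressed_intersection(tables.values()))
        else:
            shared = sorted(overexpressed_set(next(iter(tables.values()))))
        (outdir / "overexpressed_intersection.txt").write_text(
            "\n".join(shared) + ("\n" if shared else "")
        )
        outputs.append("overexpressed_intersection.txt")
        _write_json({"overexpressed_in_all_contrasts": shared}, "overexpressed_intersection.json")

    with _stage("targets"):
        table = load_targets(config.target_table_path)
        for label, de in tables.items():
            _write_tsv(annotate_de(de, table), f"de_{label}_annotated.tsv", index=False)

    with _stage("manifest"):
        manifest = {
            "nanomir_version": __version__,
            "config": config.to_dict(),
            "inputs": {str(p): _sha256(p) for p in paths},
            "design": {str(config.design_path): _sha256(config.design_path)},
            "outputs": sorted(outputs),
        }
        _write_json(manifest, "manifest.json")
    return manifest
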