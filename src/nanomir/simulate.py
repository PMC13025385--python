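"""Synthetic nCounter cohort generator with a ground-truth ledger.

The generator emits RCC lane files carrying the full control architecture of
the miRNA panel — six positive spike-ins on the 128..0.125 fM titration,
eight negative controls, six ligation controls, five mRNA reference genes —
plus a configurable number of endogenous miRNA probes, for a three-group
design (healthy control skin, BRAF wild-type tumor, BRAF-mutant tumor;
6/8/7 lanes by default).

Counts follow standard digital-counting behavior: endogenous and reference
probes draw from a negative binomial (mean = lane scale x group mean,
variance = mu + dispersion * mu^2, capturing FFPE overdispersion), negative
controls and ligation negatives from a Poisson background, positives and
ligation positives from a Poisson around lane-scaled means.  Per-lane
technical scale factors are lognormal; the normalization stages are expected
to remove them.  A ``zero_noise`` mode replaces every draw by its rounded
mean for exact-identity tests.

Planted differential effects use the signed-fold convention of the DE stage
(-17.3 means 17.3x down).  An up-planted probe sits at ``effect_baseline``
mean counts in controls and baseline x fold in both tumor groups; a
down-planted probe sits at baseline x |fold| in controls and baseline in
tumors, so planted probes stay detectable on both sides of the contrast.
Every planted quantity is recorded in a :class:`GroundTruth` ledger for
recovery scoring.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .de import signed_fold_change
from .errors import ValidationError
from .rcc import (
    CountMatrix,
    LaneRecord,
    POSITIVE_CONCENTRATIONS_FM,
    ProbeCount,
    REFERENCE_GENES,
    build_matrix,
    write_design,
    write_rcc,
)

logger = logging.getLogger(__name__)


def default_effect_map() -> dict[str, float]:
    """Planted effects mirroring the magnitudes reported for melanoma cohorts.

    Six up-regulated miRNAs (the four shared overexpressed ones plus two
    more in the 4-10x band) and 52 down-regulated ones (three named at
    10-20x down plus 49 synthetic-named probes spaced over the 4-20x band).
    """
    effects = {
        "miR-4286": 6.33,
        "miR-146a-5p": 4.19,
        "miR-4488": 3.61,
        "miR-1268a": 4.09,
        "miR-19b-3p": 4.4,
        "miR-21-5p": 5.2,
        "miR-205-5p": -17.3,
        "miR-451a": -11.6,
        "miR-203a-3p": -10.5,
    }
    for j in range(49):
        fold = round(4.0 + 16.0 * j / 48.0, 2)
        effects[f"miR-sim-dn{j + 1:02d}"] = -fold
    return effects


def _default_reference_means() -> dict[str, float]:
    return {"ACTB": 8000.0, "B2M": 12000.0, "GAPDH": 10000.0, "RPL19": 5000.0, "RPLP0": 6000.0}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_control: int = 6
    n_case_a: int = 8  # BRAF wild-type tumors
    n_case_b: int = 7  # BRAF-mutant tumors
    n_endogenous: int = 827
    baseline_log_mean: float = 3.0  # natural-log mean of lognormal abundances
    baseline_log_sd: float = 1.6  # wide spread: many probes sit below the LOD
    effect_map: dict[str, float] = field(default_factory=default_effect_map)
    effect_baseline: float = 100.0  # control-side mean counts of planted probes
    lane_scale_sigma: float = 0.4  # lognormal sigma of per-lane technical scale
    nb_dispersion: float = 0.1  # NB dispersion of endogenous/reference counts
    background_lambda: float = 12.0  # Poisson mean of negative controls
    ligation_neg_mean: float = 5.0  # below background: unligated constructs
    pos_scale: float = 250.0  # counts per fM for the positive titration
    ligation_pos_means: tuple[float, float, float] = (2000.0, 800.0, 300.0)  # A, B, C
    reference_means: dict[str, float] = field(default_factory=_default_reference_means)
    group_labels: tuple[str, str, str] = ("control", "BRAFwt", "BRAFmut")
    zero_noise: bool = False
    seed: int = 1

    def validate(self) -> None:
        if min(self.n_control, self.n_case_a, self.n_case_b) < 2:
            raise ValidationError("every group needs at least 2 lanes")
        if self.n_endogenous < len(self.effect_map):
            raise ValidationError(
                "n_endogenous smaller than the number of planted effects"
            )
        bad = {m: f for m, f in self.effect_map.items() if abs(f) < 1}
        if bad:
            raise ValidationError(f"planted folds must have magnitude >= 1: {bad}")
        if self.ligation_neg_mean <= 0:
            raise ValidationError("ligation_neg_mean must be positive")
        if self.nb_dispersion < 0 or self.background_lambda <= 0 or self.pos_scale <= 0:
            raise ValidationError("dispersion must be >=0; lambda and pos_scale positive")
        if self.lane_scale_sigma < 0:
            raise ValidationError("lane_scale_sigma must be >= 0")


@dataclass
class GroundTruth:
    """The generator's ledger: everything planted, for recovery scoring."""

    lane_scales: dict[str, float]
    planted_folds: dict[str, float]
    detectable_set: set[str]
    group_means: dict[str, dict[str, float]]
    expected_lod: float
    design: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "lane_scales": self.lane_scales,
            "planted_folds": self.planted_folds,
            "detectable_set": sorted(self.detectable_set),
            "group_means": self.group_means,
            "expected_lod": self.expected_lod,
            "design": self.design,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            lane_scales=d["lane_scales"],
            planted_folds=d["planted_folds"],
            detectable_set=set(d["detectable_set"]),
            group_means=d["group_means"],
            expected_lod=d["expected_lod"],
            design=d["design"],
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion*mu^2 (Poisson when dispersion == 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=mean.shape)


def generate_cohort(config: SyntheticConfig) -> tuple[list[LaneRecord], GroundTruth]:
    """Draw a full cohort of lane records plus its ground-truth ledger.

    The same seed yields byte-identical RCC files on rewrite.
    """
    config.validate()
    # Independent streams per probe family: changing one family's parameters
    # (e.g. pos_scale) leaves every other family's draws bit-identical.
    streams = {
        name: np.random.default_rng([config.seed, i])
        for i, name in enumerate(
            ("scales", "baseline", "positive", "negative", "ligation", "reference", "endogenous")
        )
    }
    ctrl_label, a_label, b_label = config.group_labels

    lane_ids = (
        [f"ctrl_{i + 1:02d}" for i in range(config.n_control)]
        + [f"wt_{i + 1:02d}" for i in range(config.n_case_a)]
        + [f"mut_{i + 1:02d}" for i in range(config.n_case_b)]
    )
    design = (
        {l: ctrl_label for l in lane_ids[: config.n_control]}
        | {l: a_label for l in lane_ids[config.n_control : config.n_control + config.n_case_a]}
        | {l: b_label for l in lane_ids[config.n_control + config.n_case_a :]}
    )

    # Endogenous probe panel: planted names first, synthetic fillers after.
    planted = list(config.effect_map)
    n_filler = config.n_endogenous - len(planted)
    filler = [f"miR-sim-{i + 1:04d}" for i in range(n_filler)]
    endo_names = planted + filler

    filler_means = np.exp(
        streams["baseline"].normal(
            config.baseline_log_mean, config.baseline_log_sd, size=n_filler
        )
    )
    ctrl_means: dict[str, float] = {}
    case_means: dict[str, float] = {}
    for name in planted:
        fold = config.effect_map[name]
        if fold > 0:
            ctrl_means[name] = config.effect_baseline
            case_means[name] = config.effect_baseline * fold
        else:
            ctrl_means[name] = config.effect_baseline * abs(fold)
            case_means[name] = config.effect_baseline
    for name, m in zip(filler, filler_means):
        ctrl_means[name] = float(m)
        case_means[name] = float(m)

    if config.zero_noise:
        lane_scales = {l: 1.0 for l in lane_ids}
        expected_lod = float(np.rint(config.background_lambda))
    else:
        lane_scales = {
            l: float(np.exp(streams["scales"].normal(0.0, config.lane_scale_sigma)))
            for l in lane_ids
        }
        expected_lod = config.background_lambda + 2.0 * math.sqrt(config.background_lambda)

    def _round(x: np.ndarray) -> np.ndarray:
        return np.rint(np.asarray(x, dtype=float)).astype(int)

    lanes: list[LaneRecord] = []
    for lane_id in lane_ids:
        s = lane_scales[lane_id]
        group = design[lane_id]
        probes: list[ProbeCount] = []

        for letter, fm in POSITIVE_CONCENTRATIONS_FM.items():
            mu = config.pos_scale * fm * s
            c = int(np.rint(mu)) if config.zero_noise else int(streams["positive"].poisson(mu))
            probes.append(
                ProbeCount(f"POS_{letter}", "Positive", f"SYN_POS_{letter}", c, fm)
            )
        for i in range(8):
            mu = config.background_lambda
            c = int(np.rint(mu)) if config.zero_noise else int(streams["negative"].poisson(mu))
            probes.append(ProbeCount(f"NEG_{chr(65 + i)}", "Negative", f"SYN_NEG_{i}", c))
        for letter, mu0 in zip("ABC", config.ligation_pos_means):
            mu = mu0 * s
            c = int(np.rint(mu)) if config.zero_noise else int(streams["ligation"].poisson(mu))
            probes.append(ProbeCount(f"LIG_POS_{letter}", "Ligation", f"SYN_LIGP_{letter}", c))
        for letter in "ABC":
            mu = config.ligation_neg_mean
            c = int(np.rint(mu)) if config.zero_noise else int(streams["ligation"].poisson(mu))
            probes.append(ProbeCount(f"LIG_NEG_{letter}", "Ligation", f"SYN_LIGN_{letter}", c))
        for gene in REFERENCE_GENES:
            mu = config.reference_means[gene] * s
            c = (
                int(np.rint(mu))
                if config.zero_noise
                else int(_nb_draw(streams["reference"], np.array([mu]), config.nb_dispersion)[0])
            )
            probes.append(ProbeCount(gene, "Housekeeping", f"SYN_REF_{gene}", c))

        base = ctrl_means if group == ctrl_label else case_means
        mus = np.array([base[n] for n in endo_names]) * s
        counts = (
            _round(mus)
            if config.zero_noise
            else _nb_draw(streams["endogenous"], mus, config.nb_dispersion)
        )
        for name, c in zip(endo_names, counts):
            probes.append(ProbeCount(name, "Endogenous", f"SYN_{name}", int(c)))

        lanes.append(
            LaneRecord(
                lane_id=lane_id,
                sample_attributes={
                    "Header.FileVersion": "1.7",
                    "Header.SoftwareVersion": "nanomir-synthetic",
                    "Sample_Attributes.ID": lane_id,
                    "Sample_Attributes.Owner": "synthetic",
                    "Sample_Attributes.GeneRLF": "miRNA_v3_synthetic",
                    "Lane_Attributes.ID": lane_id,
                },
                probes=probes,
            )
        )

    if config.zero_noise:
        detectable = {
            n
            for n in endo_names
            if np.rint(ctrl_means[n]) > expected_lod and np.rint(case_means[n]) > expected_lod
        }
    else:
        detectable = {
            n
            for n in endo_names
            if ctrl_means[n] > expected_lod and case_means[n] > expected_lod
        }

    truth = GroundTruth(
        lane_scales=lane_scales,
        planted_folds=dict(config.effect_map),
        detectable_set=detectable,
        group_means={
            ctrl_label: {n: ctrl_means[n] for n in endo_names},
            a_label: {n: case_means[n] for n in endo_names},
            b_label: {n: case_means[n] for n in endo_names},
        },
        expected_lod=expected_lod,
        design=design,
    )
    return lanes, truth


def cohort_matrix(lanes: Sequence[LaneRecord], truth: GroundTruth) -> CountMatrix:
    """Convenience: assemble a generated cohort into a CountMatrix."""
    return build_matrix(lanes, truth.design)


def write_cohort(
    lanes: Sequence[LaneRecord], truth: GroundTruth, outdir
) -> dict[str, str]:
    """Write RCC files, the design TSV, and the truth ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lane in lanes:
        p = outdir / f"{lane.lane_id}.rcc"
        write_rcc(lane, p)
        paths[lane.lane_id] = str(p)
    write_design(truth.design, outdir / "design.tsv")
    truth.to_json(outdir / "truth.json")
    return paths


def evaluate_recovery(
    truth: GroundTruth,
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    pos_factors: Optional[pd.Series] = None,
) -> dict:
    """Score a DE table against the ledger.

    Reports per-miRNA planted vs observed fold changes, the sensitivity /
    specificity / Jaccard of the significant call at the given threshold,
    the false-positive rate among non-planted probes, and (when positive
    factors are supplied) the relative spread of factor x true-scale, which
    is constant under perfect lane-factor recovery.
    """
    observed = results.set_index("mirna")
    planted_sig = {m for m, f in truth.planted_folds.items() if abs(f) > fc_threshold}
    called_sig = set(observed.index[observed["significant"]])

    rows = []
    for m, f in sorted(truth.planted_folds.items()):
        obs = float(observed.loc[m, "fold_change"]) if m in observed.index else math.nan
        rel = abs(obs - f) / abs(f) if math.isfinite(obs) else math.nan
        rows.append({"mirna": m, "planted_fold": f, "observed_fold": obs, "rel_error": rel})
    per_mirna = pd.DataFrame(
        rows, columns=["mirna", "planted_fold", "observed_fold", "rel_error"]
    )
    rel_errors = per_mirna["rel_error"].dropna()

    tp = len(called_sig & planted_sig)
    fn = len(planted_sig - called_sig)
    non_planted = set(observed.index) - set(truth.planted_folds)
    fp = len(called_sig & non_planted)
    tn = len(non_planted - called_sig)

    report = {
        "per_mirna": per_mirna,
        "median_rel_fc_error": float(rel_errors.median()) if len(rel_errors) else math.nan,
        "sensitivity": tp / len(planted_sig) if planted_sig else math.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else math.nan,
        "jaccard": (
            len(called_sig & planted_sig) / len(called_sig | planted_sig)
            if (called_sig | planted_sig)
            else 1.0
        ),
        "false_positive_rate": fp / len(non_planted) if non_planted else math.nan,
        "n_planted_significant": len(planted_sig),
        "n_called_significant": len(called_sig),
    }
    if pos_factors is not None:
        v = np.array(
            [pos_factors[l] * truth.lane_scales[l] for l in pos_factors.index]
        )
        report["lane_factor_recovery_error"] = float((v.max() - v.min()) / v.mean())
    return report
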