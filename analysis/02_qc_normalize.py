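#!/usr/bin/env python
"""Lane QC and dual-stage normalization of the synthetic cohort.

Reads the RCC files written by 01_simulate_cohort.py (regenerating them if
absent), computes per-lane LODs, both normalization factor sets with their
flag ranges, and the control-rule verdicts, then writes the normalized
matrix.  The QC table goes to results/; the full normalized matrix is bulky
and goes to scratch/.
"""

from pathlib import Path

import nanomir as nm
from nanomir.qc import cohort_qc, dual_normalize, qc_table

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def load_cohort():
    cohort = ROOT / "scratch" / "cohort"
    if not cohort.exists():
        lanes, truth = nm.generate_cohort(nm.SyntheticConfig(seed=SEED))
        nm.write_cohort(lanes, truth, cohort)
    paths = sorted(cohort.glob("*.rcc"))
    lanes = [nm.read_rcc(p) for p in paths]
    design = nm.read_design(cohort / "design.tsv")
    return nm.build_matrix(lanes, design), nm.GroundTruth.from_json(cohort / "truth.json")


def main() -> None:
    matrix, _ = load_cohort()
    qdf = qc_table(cohort_qc(matrix))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    qdf.to_csv(results / "02_lane_qc.tsv", sep="\t")

    norm, pos, content = dual_normalize(matrix)
    (ROOT / "scratch").mkdir(exist_ok=True)
    norm.counts.to_csv(ROOT / "scratch" / "normalized_matrix.tsv", sep="\t")

    print(f"{len(qdf)} lanes; LOD range {qdf.lod.min():.1f}-{qdf.lod.max():.1f} counts")
    print(f"positive factors {pos.min():.3f}-{pos.max():.3f} "
          f"({int(qdf.pos_factor_flagged.sum())} flagged outside 0.3-3.0)")
    print(f"content factors {content.min():.3f}-{content.max():.3f} "
          f"({int(qdf.content_factor_flagged.sum())} flagged outside 0.1-10.0)")
    print(f"POS_E above background in all lanes: {bool(qdf.pose_above_background.all())}; "
          f"ligation controls pass in all lanes: {bool(qdf.ligation_pass.all())}")
    print(f"positive titration linearity R^2 >= {qdf.pos_linearity_r2.min():.4f}")


if __name__ == "__main__":
    main()
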