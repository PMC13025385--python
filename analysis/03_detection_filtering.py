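#!/usr/bin/env python
"""LOD-based detection summaries and the >50% prevalence filter.

For each tumor-vs-control contrast this reports, over the union of the
contrast's lanes, how many endogenous miRNAs are detected in at least one
lane, in more than half, and in every lane (the study's detection summary
shape), and how many survive the strict >50% prevalence filter that feeds
differential expression.
"""

import importlib
import json
import sys
from pathlib import Path

import nanomir as nm
from nanomir.detection import detect, prevalence_filter, summarize
from nanomir.qc import dual_normalize, lane_lods

sys.path.insert(0, str(Path(__file__).resolve().parent))
load_cohort = importlib.import_module("02_qc_normalize").load_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    matrix, _ = load_cohort()
    norm, _, _ = dual_normalize(matrix)
    det = detect(norm, lane_lods(matrix))

    report = {}
    for case in ("BRAFwt", "BRAFmut"):
        union = matrix.lanes_in_group(case) + matrix.lanes_in_group("control")
        s = summarize(det, union)
        retained = prevalence_filter(det, union)
        report[f"{case}_vs_control"] = s.to_dict() | {"retained_for_de": len(retained)}
        print(f"{case} + controls ({len(union)} lanes): "
              f"{s.n_detected_any} miRNAs in >=1 lane, "
              f"{s.n_detected_majority} in >50%, {s.n_detected_all} in all; "
              f"{len(retained)} retained for DE")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "03_detection_summary.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
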