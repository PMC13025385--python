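#!/usr/bin/env python
"""Annotate the shared overexpressed miRNAs with validated target genes.

Joins the cross-contrast overexpression intersection to the packaged table
of curated miRNA-target interactions and reports, for the two headline
miRNAs, their validated targets and the genes they share — the regulatory
convergence the target analysis looks for.
"""

import json
from pathlib import Path

from nanomir.targets import load_targets, shared_targets, targets_of

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = load_targets()
    headline = ["miR-146a-5p", "miR-4286"]
    report = {
        "validated_targets": {
            m: sorted(targets_of(table, m, "validated")) for m in headline
        },
        "predicted_targets": {
            m: sorted(targets_of(table, m, "predicted")) for m in headline
        },
        "shared_targets": sorted(shared_targets(table, headline)),
    }

    for m in headline:
        print(f"{m}: validated targets {', '.join(report['validated_targets'][m])}")
    print(f"shared by both: {', '.join(report['shared_targets'])}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "05_shared_targets.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
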