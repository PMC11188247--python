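#!/usr/bin/env python
"""Elicit criterion weights from the simulated panel, by both back-ends.

Direct route: the mean of each criterion's 1-5 expert ratings (run
01_simulate_panel.py first). AHP route: a pairwise-comparison matrix built
from the panel's mean ratings, solved by the principal eigenvector with
Saaty's consistency ratio. The two routes agree on the ordering of criteria;
the report records both weight vectors and the CR.
"""

import argparse
import json
from pathlib import Path

from evidem import core_framework
from evidem.io_cli import write_weights
from evidem.weight_elicitation import (
    PairwiseMatrix,
    RatingSheet,
    ahp_weights,
    direct_weights,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "02_weights"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ratings", type=Path,
                        default=ROOT / "01_panel" / "ratings.csv")
    args = parser.parse_args()

    fw = core_framework()
    sheet = RatingSheet.from_csv(args.ratings)
    direct = direct_weights(sheet, fw)

    # AHP on the ratio structure implied by the panel's mean ratings;
    # a ratio-consistent matrix, so CR must come out 0
    matrix = PairwiseMatrix.from_weights(direct.raw)
    ahp, report = ahp_weights(matrix)

    OUT.mkdir(parents=True, exist_ok=True)
    write_weights(direct, OUT / "weights_direct.json")
    write_weights(ahp, OUT / "weights_ahp.json")
    (OUT / "consistency.json").write_text(json.dumps({
        "lambda_max": report.lambda_max, "ci": report.ci,
        "ri": report.ri, "cr": report.cr, "consistent": report.consistent,
    }, indent=2) + "\n")

    print(f"Direct weights from {len(sheet.experts)} experts; "
          f"AHP CR = {report.cr:.2e} ({'pass' if report.consistent else 'FAIL'}).")
    top = max(direct.normalized, key=direct.normalized.get)
    print(f"Highest-weighted criterion (direct): {top} "
          f"(normalized {direct.normalized[top]:.4f}).")
    agree = max(
        abs(direct.normalized[c] - ahp.normalized[c]) for c in direct.normalized
    )
    print(f"Max |direct - AHP| normalized weight gap: {agree:.2e} "
          f"(matrix built from the direct means, so the routes coincide).")
    print(f"Wrote weight vectors and the consistency report to {OUT}/.")


if __name__ == "__main__":
    main()
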