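#!/usr/bin/env python
"""Value the two acid blockers on the published panel scores.

Computes the additive value V = sum_x (W_x / sum W) S_x, S_x = score/5, for
vonoprazan and tegoprazan under uniform weights, decomposes it by criterion
and domain, checks the relative-scoring consensus cap, and ranks the domains
by value-contribution difference.
"""

import json
from pathlib import Path

from evidem import (
    WeightVector,
    compare_interventions,
    compute_value,
    core_framework,
)
from evidem.panel_scoring import (
    NO_SIGNIFICANT_DIFFERENCE,
    SignificanceMap,
    validate_relative_rule,
)
from evidem.synthetic_data import reference_panel_scores

OUT = Path(__file__).resolve().parent.parent / "results" / "03_values"


def main() -> None:
    fw = core_framework()
    summaries = reference_panel_scores()
    weights = WeightVector.uniform(fw)

    breakdowns = {n: compute_value(weights, s, fw) for n, s in summaries.items()}
    comparison = compare_interventions(breakdowns["VPZ"], breakdowns["TPZ"])
    sig = SignificanceMap({
        "comparative_effectiveness": NO_SIGNIFICANT_DIFFERENCE,
        "comparative_safety": NO_SIGNIFICANT_DIFFERENCE,
        "patient_perceived_health": NO_SIGNIFICANT_DIFFERENCE,
    })
    violations = validate_relative_rule(summaries["VPZ"], summaries["TPZ"], sig, fw)

    OUT.mkdir(parents=True, exist_ok=True)
    for name, bd in breakdowns.items():
        bd.to_json(OUT / f"value_{name}.json")
        (OUT / f"value_{name}.md").write_text(bd.to_markdown(fw))
    (OUT / "comparison.json").write_text(
        json.dumps(comparison.to_dict(), indent=2) + "\n")

    print("Uniform-weight totals (display / full precision):")
    for name, bd in breakdowns.items():
        print(f"  {name}: {bd.total_display:.2f} ({bd.total:.4f})")
    print(f"Consensus-cap violations on comparative criteria: {len(violations)}.")
    print("Domains ranked by |value-contribution difference| (VPZ - TPZ):")
    for rank, did in enumerate(comparison.ranked_domains, 1):
        print(f"  {rank}. {fw.domain_name(did)}: "
              f"{comparison.domain_deltas[did]:+.4f}")
    print(f"Wrote breakdowns and the comparison to {OUT}/.")


if __name__ == "__main__":
    main()
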