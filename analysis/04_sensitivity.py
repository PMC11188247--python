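#!/usr/bin/env python
"""Uncertainty and one-way weight sensitivity of the value gap.

Monte Carlo: samples every criterion mean from a truncated normal
(mean +/- SD from the published panel summary, truncated to the scale) and
reports the distribution of both totals and the probability that vonoprazan
outscores tegoprazan. Tornado: shifts each raw weight by +/-1 on the 1-5
scale and ranks criteria by the induced swing of the value gap.
"""

import argparse
import json
from pathlib import Path

from evidem import WeightVector, core_framework
from evidem.analysis import monte_carlo_values, tornado_weights
from evidem.synthetic_data import reference_panel_scores

OUT = Path(__file__).resolve().parent.parent / "results" / "04_sensitivity"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--draws", type=int, default=10_000)
    parser.add_argument("--delta", type=float, default=1.0)
    args = parser.parse_args()

    fw = core_framework()
    summaries = reference_panel_scores()
    weights = WeightVector.uniform(fw)

    mc = monte_carlo_values(summaries["VPZ"], summaries["TPZ"], weights, fw,
                            n_draws=args.draws, seed=args.seed)
    tr = tornado_weights(weights, summaries["VPZ"], summaries["TPZ"], fw,
                         delta=args.delta)

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "monte_carlo.json").write_text(json.dumps(mc.to_dict(), indent=2) + "\n")
    (OUT / "tornado.json").write_text(json.dumps(tr.to_dict(), indent=2) + "\n")

    a, b = mc.interventions
    print(f"Monte Carlo ({args.draws} draws, seed {args.seed}):")
    for name in (a, b):
        lo, hi = mc.percentiles[name]
        print(f"  {name}: mean V = {mc.means[name]:.4f}, 95% interval "
              f"[{lo:.4f}, {hi:.4f}]")
    print(f"  P({a} > {b}) = {mc.p_a_gt_b:.3f} -- the ranking is robust to the "
          "panel's score dispersion when that probability is near 1.")
    print(f"Tornado (delta = {args.delta} on raw weights), top 3 criteria by "
          "swing of the value gap:")
    for e in tr.entries[:3]:
        print(f"  {e.criterion_id}: {e.delta_diff:+.4f}")
    print(f"Wrote both analyses to {OUT}/.")


if __name__ == "__main__":
    main()
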