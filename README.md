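# evidem-mcda

Multicriteria decision analysis (MCDA) for hospital drug appraisal, built
around the EVIDEM value framework. The package was written to support
Pharmacy & Therapeutics Committee (PTC) style formulary decisions — here,
valuing two potassium-competitive acid blockers, vonoprazan (VPZ) and
tegoprazan (TPZ), against the proton-pump-inhibitor (PPI) standard of care
for gastroesophageal reflux disease — but every stage is generic over a
configurable framework of domains and criteria.

## The model

The framework's core model has 5 domains and 13 criteria. *Absolute*
criteria are scored 0–5 against a fixed anchor; *relative* criteria are
scored −5…+5 against the comparator class. Given raw criterion weights
$W_x > 0$ and a panel's mean scores, the total value of an intervention is
the additive linear aggregate

$$V \;=\; \sum_x V_x \;=\; \sum_x \frac{W_x}{\sum_n W_n}\, S_x,
\qquad S_x = \frac{\text{score}_x}{5},$$

so each criterion contributes its normalized weight times its normalized
score and $V \in [-1, 1]$. The package implements, end to end:

* **core model** — framework definition (YAML), the value computation with
  per-criterion and per-domain decomposition, and intervention comparison
  with domain-gap ranking (`evidem.core_model`);
* **weight elicitation** — direct 1–5 impact ratings averaged over experts,
  or the analytic hierarchy process (principal eigenvector of a pairwise
  matrix with Saaty's consistency ratio CR = CI/RI,
  CI = (λ_max − n)/(n − 1)) (`evidem.weight_elicitation`);
* **panel scoring** — aggregation of per-expert integer scores to
  mean ± SD (sample SD), the ≤1-point consensus cap on relative criteria
  judged not significantly different, and the missing-evidence policy
  (score 0, weight kept in the sum) (`evidem.panel_scoring`);
* **analysis** — Monte Carlo propagation of score dispersion through
  truncated normals, tornado (one-way) weight sensitivity, and inverse
  calibration of a weight vector against published headline values under
  qualitative ordering constraints (`evidem.analysis`);
* **synthetic data** — a seeded generator for whole expert panels plus the
  bundled published score table for the VPZ/TPZ appraisal
  (`evidem.synthetic_data`);
* **I/O and CLI** — YAML/CSV/JSON readers and writers and the `evidem`
  command-line pipeline (`evidem.io_cli`).

## Worked example

```python
from evidem import WeightVector, compare_interventions, compute_value, core_framework
from evidem.synthetic_data import reference_panel_scores

fw = core_framework()                 # 5 domains, 13 criteria
scores = reference_panel_scores()     # published VPZ/TPZ panel means ± SDs
weights = WeightVector.uniform(fw)    # all raw weights equal

for name, summary in scores.items():
    bd = compute_value(weights, summary, fw)
    print(name, f"{bd.total_display:.2f}", f"({bd.total:.4f})")

cmp = compare_interventions(
    compute_value(weights, scores["VPZ"], fw),
    compute_value(weights, scores["TPZ"], fw),
)
print(cmp.ranked_domains[0], f"{cmp.domain_deltas['economic']:+.4f}")
```

prints

```
VPZ 0.55 (0.5508)
TPZ 0.49 (0.4923)
economic +0.0431
```

Under equal weights VPZ's value is 35.8/65 ≈ 0.55 and TPZ's 32.0/65 ≈ 0.49
(each total is the sum of the 13 mean scores divided by 5 × 13), and the
largest value-contribution gap between the drugs sits in the economic
domain — drug costs (0.9 vs −0.6) and other medical costs (1.3 vs 0, no
evidence for TPZ).

The published appraisal reported 0.59 and 0.54 using the panel's own
(graphically reported) weights; `evidem.analysis.calibrate_weights`
recovers a weight vector in [1, 5] consistent with the panel's qualitative
weight structure that reproduces that pair exactly (see
`analysis/05_calibrate_weights.py`).

## Analysis scripts

The `analysis/` directory holds the numbered drivers for the full appraisal,
each writing its tables under `results/`:

1. `01_simulate_panel.py` — synthetic 14-expert panel (ratings + scores);
2. `02_elicit_weights.py` — direct and AHP weights with consistency report;
3. `03_compute_values.py` — value breakdowns, consensus-cap check, domain ranking;
4. `04_sensitivity.py` — Monte Carlo and tornado analyses;
5. `05_calibrate_weights.py` — inverse weight calibration to the headline pair.

There is also a CLI: `evidem run --config <yaml>` executes the whole
pipeline; `evidem weights|aggregate|value|compare|mc|tornado|calibrate|simulate`
expose the individual stages (`evidem --help`).

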