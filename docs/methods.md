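# Methods

## The value model and its assumptions

The package aggregates evidence about a health technology into a single
value score with an additive linear model over a fixed framework of 5
domains and 13 criteria. Each criterion $x$ carries a raw weight $W_x > 0$
and a panel mean score on its own scale; the score is normalized as
$S_x = \text{score}_x / 5$ and the total value is

$$V = \sum_x \frac{W_x}{\sum_n W_n} S_x .$$

The sum runs over the framework's criteria. (The source formulation is
ambiguous about the index — its prose attaches $n$ to the number of panel
experts — but the arithmetic is only coherent as a sum over criteria, and
that is the reading implemented and tested here.)

Assumptions inherited from the additive form: criteria are preferentially
independent and contribute proportionally — there are no interaction terms,
and a 1-point score change is worth the same anywhere on the scale. Absolute
criteria (0–5) can only add value; relative criteria (−5…+5) can subtract
it, so $V \in [-1, 1]$ in general and $[0, 1]$ for an all-absolute
framework. Normalizing weights by their sum makes $V$ invariant to rescaling
all raw weights by a positive constant; the property suite checks this to
1e−12.

## Weight elicitation

**Direct rating.** Each expert rates each criterion's impact on the value of
a medicine on an integer 1–5 scale (5 = decisive … 1 = inessential); the raw
weight is the mean rating. Ratings must be integers in [1, 5]; violations
name the expert and criterion.

**AHP.** Weights are the principal right eigenvector of a positive
reciprocal pairwise matrix, computed by power iteration (relative change
< 1e−10, at most 10 000 iterations; non-convergence is a hard error).
The eigenvector method is used rather than the row geometric mean because it
is the canonical formulation; the geometric-mean variant could be added
behind the same interface. Consistency is reported as CI = (λ_max − n)/(n − 1)
and CR = CI/RI with Saaty's tabulated random indices for orders 1–15
(orders beyond 15 are rejected; CR is undefined below order 3 and CI is
reported alone there). The conventional acceptance threshold CR ≤ 0.1 is the
default but configurable. Several experts' matrices are combined by the
element-wise geometric mean before extraction (aggregation of individual
judgments), the standard choice when a single consensus matrix is wanted.

Both back-ends produce the same `WeightVector` type, selected by config: the
source appraisal describes a 5-point weighting tool *and* AHP without
stating precisely how they were combined, so neither path is privileged.

## Panel scoring

Panel summaries are the arithmetic mean and the sample standard deviation
(n−1 denominator) of the experts' integer scores; the sample SD was chosen
as the small-panel convention, and since the bundled published summary
stores printed values verbatim, the choice only affects newly aggregated
panels. A single-expert panel yields SD 0 with a warning rather than an
error, keeping toy examples runnable. Display rounding is 1 decimal for
mean ± SD and 2 decimals for V, half-up (ties away from zero); all internal
arithmetic is full precision. Half-up was chosen because the published
display values are consistent with it; the alternative (truncation) is not
used anywhere.

**Consensus cap.** For relative criteria where the evidence shows no
significant difference between the two interventions (each judged via the
common comparator), the panel's rule caps the score difference at 1 point.
The cap is enforced on panel means — the only published quantities — with a
strict per-expert mode available when raw sheets exist.

**Missing evidence.** A criterion with no retrieved evidence scores 0 with
SD 0 and a `no-evidence` annotation; its weight stays in $\sum W_n$ (the
published table records 0 rather than excluding the row, and renormalizing
would silently inflate every other criterion). Evidence-quality flags are
annotations only: quality is routed through the framework's own 'quality of
evidence' criterion, not through score modulation.

## Monte Carlo uncertainty

Only mean ± SD summaries are published, so score uncertainty is modeled as a
normal on the panel mean truncated to the criterion's scale bounds
(`scipy.stats.truncnorm`), independent across criteria and interventions —
mirroring the additive model's independence assumption. Per draw, $V$ is
computed for both interventions; the headline output is
$P(V_a > V_b)$, the probability the ranking survives score uncertainty.
With SD → 0 the sampler collapses to the mean, and identical seeds and
inputs give bitwise-identical results. Resampling per-expert integer scores
is possible when raw sheets exist (generate them with the synthetic panel),
but the default uses exactly the printed information. Note that truncation
shifts the sampled mean toward the scale interior for criteria near a bound,
so the MC mean of $V$ sits slightly below the deterministic value here;
this is a property of the truncated model, not an error.

## Tornado analysis

One raw weight at a time is shifted by ±δ (default 1 on the 1–5 raw scale,
clipped into the bounds; pass `bounds=None` to merely floor at 0), the
weights renormalize implicitly, and both totals are recomputed. Criteria are
ranked by the absolute swing of the gap $V_a - V_b$ between the + and −
perturbation, ties broken by framework order. Perturbing a criterion on
which both interventions score identically rescales the gap by a positive
factor and can never flip its sign.

## Inverse weight calibration

The published appraisal reports its weight vector only graphically, so the
headline value pair cannot be recomputed directly. Instead the calibration
routine asks: does *some* raw weight vector in $[1,5]^{13}$ satisfy the
published qualitative weight structure —

* unmet needs weighted strictly above the other two criteria of its domain,
* comparative effectiveness and safety weighted exactly equally,
* drug costs > other medical costs > non-medical costs (strict, margin
  1e−9) —

and make both drugs' values round (half-up, 2 decimals) to the published
pair simultaneously? The search is deterministic and seed-free: a coarse
grid (5, 3 or 2 levels per free weight, chosen so the grid stays under
2×10⁶ points; equality-linked criteria share one free variable) filtered by
the constraints, then SLSQP refinement of the squared residual to the
unrounded targets, bounded to $[1,5]$ with the strict constraints held at a
1e−6 margin. If refinement leaves the feasible region the grid candidate is
kept. Success requires exact rounded equality on both targets jointly;
otherwise an infeasibility report returns the closest achieved pair.
Internally contradictory constraint systems (a strict cycle through the
equality-merged graph) are rejected up front.

Calibration establishes *joint feasibility* — the published scores, weight
structure and headline pair are mutually consistent — not the panel's true
weights; many vectors in the feasible set reproduce the pair.

## Synthetic panels

The generator emulates the appraisal's panel: 14 experts (two per hospital
discipline), each emitting an integer 1–5 rating per criterion and an
integer score per criterion–intervention, by sampling
Normal(latent mean, SD), rounding to the nearest integer and clipping to
the bounds. Defaults: `n_experts = 14`; rating SD 0.8, which yields
aggregated SDs in the 0.5–1.2 range of the published table; latent score
means/SDs equal the published summary; latent rating means encode the
reported qualitative weight ordering (unmet needs 5; effectiveness = safety
= 4; costs 4 > other 3 > non-medical 2; remaining criteria 3–4). Round-then-
clip is used instead of rejection sampling for simplicity; it biases
aggregated means by at most ≈0.15 for means near a bound or mid-integer, and
the parameter-recovery tests budget exactly 3·SD/√n + 0.15. What the
generator does **not** model: inter-expert correlation from shared panel
discussion, expert covariates, and discipline-specific scoring styles — so
passing recovery tests show the pipeline's arithmetic is sound under
independence, not that real panel dynamics are captured.

## Numerical and I/O conventions

* All CSVs: comma-separated, UTF-8, mandatory header, `.` decimal separator,
  `#` comment lines allowed on input; the canonical score-summary writer is
  byte-deterministic so fixtures round-trip identically.
* Currency enters the affordability computation as exact decimals
  (`decimal.Decimal` over stringified amounts), so two-digit amounts never
  drift: share = 100·cost/income, half-up at 1 decimal.
* Pipeline reports are JSON plus a markdown rendering of the same numbers;
  given the same config and seed the JSON is identical apart from its
  timestamp field, and every input file is logged with a SHA-256 digest.
* Degenerate inputs: empty panels and empty weight vectors are structural
  errors; SD = 0 is valid everywhere and means "the panel was unanimous".

## Problem sizes used in the shipped analyses

The bundled drivers and the acceptance script run the full 13-criterion
framework: calibration scans ≈1.6×10⁶ grid points (3 levels, 12 free
weights after the equality merge) in a couple of seconds; Monte Carlo uses
10 000 draws (MC standard error on $P(a>b)$ ≈ 0.005); synthetic-panel
recovery tests use 200 experts. These sizes make every result reproducible
on a laptop in seconds.

## Known limitations

* The additive model cannot express criterion interactions or diminishing
  returns; it is the intended model here, not a simplification of one.
* The calibrated weight vector is one witness from a feasible set, not an
  estimate of the panel's weights.
* The 1-point consensus cap binds panel means by default; the published
  record does not state whether the panel enforced it per expert.
* AHP consistency indices are only tabulated to order 15.
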