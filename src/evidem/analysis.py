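"""Uncertainty and sensitivity analysis over the additive value model.

Three tools:

* **Monte Carlo value distribution** — propagates the panel's score
  dispersion (mean +/- SD per criterion) through the value model. Each draw
  samples every criterion mean from a normal truncated to the criterion's
  scale bounds, independently across criteria and interventions, and records
  both interventions' totals; the rank-reversal probability is the fraction
  of draws in which intervention *a* outscores *b*.
* **Tornado (one-way weight) analysis** — perturbs one raw weight at a time
  by +/- delta (renormalizing) and ranks criteria by how much the value gap
  between the two interventions moves.
* **Inverse weight calibration** — searches for a raw weight vector in
  [1, 5] that satisfies qualitative ordering constraints and whose model
  values, rounded at a stated precision, jointly hit target values for both
  interventions. The search is deterministic: a coarse grid over the
  constraint-feasible region followed by bounded least-squares refinement of
  the round-trip error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .core_model import (
    FrameworkDefinition,
    ScoreSummary,
    WeightVector,
    compute_value,
    round_half_up,
)
from .errors import StructuralError, ValidationError

__all__ = [
    "MonteCarloResult",
    "TornadoResult",
    "TornadoEntry",
    "OrderingConstraint",
    "CalibrationProblem",
    "CalibrationResult",
    "monte_carlo_values",
    "tornado_weights",
    "calibrate_weights",
]


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloResult:
    n_draws: int
    seed: int
    interventions: tuple[str, str]
    means: Mapping[str, float]           # intervention -> mean of sampled V
    percentiles: Mapping[str, tuple[float, float]]  # 2.5 / 97.5
    p_a_gt_b: float

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "interventions": list(self.interventions),
            "means": dict(self.means),
            "percentiles": {k: list(v) for k, v in self.percentiles.items()},
            "p_a_gt_b": self.p_a_gt_b,
        }


def _sample_truncated(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, upper: float, size: int) -> np.ndarray:
    """Truncated-normal draws; sd = 0 collapses to the (clipped) mean."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def monte_carlo_values(summary_a: ScoreSummary, summary_b: ScoreSummary,
                       weights: WeightVector, framework: FrameworkDefinition,
                       n_draws: int = 10_000, seed: int = 0) -> MonteCarloResult:
    """Sample score uncertainty and summarize the induced value distributions.

    Per draw, each criterion's mean score is sampled from
    Normal(mean, sd) truncated to the criterion's scale, independently across
    the 13 criteria and the two interventions. Identical seeds and inputs give
    bitwise-identical results.
    """
    if not isinstance(n_draws, (int, np.integer)) or n_draws < 1:
        raise ValidationError(f"n_draws must be a positive integer, got {n_draws!r}")
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValidationError(f"seed must be a non-negative integer, got {seed!r}")
    weights.align(framework)
    summary_a.validate_against(framework)
    summary_b.validate_against(framework)

    rng = np.random.default_rng(int(seed))
    norm_w = weights.normalized
    w = np.array([norm_w[c.id] for c in framework.criteria])

    totals = {}
    for summary in (summary_a, summary_b):
        draws = np.empty((n_draws, len(framework.criteria)))
        for j, c in enumerate(framework.criteria):
            draws[:, j] = _sample_truncated(
                rng, summary.means[c.id], summary.sds[c.id],
                c.scale.lower, c.scale.upper, n_draws,
            )
        totals[summary.intervention] = (draws / 5.0) @ w

    va, vb = totals[summary_a.intervention], totals[summary_b.intervention]
    return MonteCarloResult(
        n_draws=int(n_draws),
        seed=int(seed),
        interventions=(summary_a.intervention, summary_b.intervention),
        means={k: float(v.mean()) for k, v in totals.items()},
        percentiles={
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in totals.items()
        },
        p_a_gt_b=float(np.mean(va > vb)),
    )


# ---------------------------------------------------------------------------
# Tornado (one-way weight sensitivity)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    criterion_id: str
    v_a_plus: float
    v_a_minus: float
    v_b_plus: float
    v_b_minus: float

    @property
    def delta_diff(self) -> float:
        """Swing of the value gap (V_a - V_b) between the + and - perturbation."""
        return (self.v_a_plus - self.v_b_plus) - (self.v_a_minus - self.v_b_minus)


@dataclass(frozen=True)
class TornadoResult:
    delta: float
    base_v_a: float
    base_v_b: float
    entries: tuple[TornadoEntry, ...]  # ranked by |delta_diff|, descending

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "base_v_a": self.base_v_a,
            "base_v_b": self.base_v_b,
            "entries": [
                {
                    "criterion_id": e.criterion_id,
                    "v_a_plus": e.v_a_plus, "v_a_minus": e.v_a_minus,
                    "v_b_plus": e.v_b_plus, "v_b_minus": e.v_b_minus,
                    "delta_diff": e.delta_diff,
                }
                for e in self.entries
            ],
        }


def tornado_weights(weights: WeightVector, summary_a: ScoreSummary,
                    summary_b: ScoreSummary, framework: FrameworkDefinition,
                    delta: float = 1.0,
                    bounds: tuple[float, float] | None = (1.0, 5.0),
                    ) -> TornadoResult:
    """One-way weight sensitivity of both totals and of their gap.

    Each criterion's raw weight is shifted by +delta and -delta (weights are
    renormalized implicitly by the value model). With ``bounds`` set (default
    the 1-5 rating scale) the shifted weight is clipped into the bounds;
    without bounds it is floored just above 0. Entries are ranked by the
    absolute swing of V_a - V_b, framework order breaking ties.
    """
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    weights.align(framework)
    base_a = compute_value(weights, summary_a, framework)
    base_b = compute_value(weights, summary_b, framework)

    def clip(w: float) -> float:
        if bounds is not None:
            return float(min(max(w, bounds[0]), bounds[1]))
        return float(max(w, 1e-9))

    entries = []
    for c in framework.criteria:
        perturbed = {}
        for sign in (+1, -1):
            raw = dict(weights.raw)
            raw[c.id] = clip(raw[c.id] + sign * delta)
            wv = WeightVector(raw)
            perturbed[sign] = (
                compute_value(wv, summary_a, framework).total,
                compute_value(wv, summary_b, framework).total,
            )
        entries.append(TornadoEntry(
            criterion_id=c.id,
            v_a_plus=perturbed[+1][0], v_b_plus=perturbed[+1][1],
            v_a_minus=perturbed[-1][0], v_b_minus=perturbed[-1][1],
        ))

    order = {c.id: i for i, c in enumerate(framework.criteria)}
    ranked = tuple(sorted(
        entries, key=lambda e: (-abs(e.delta_diff), order[e.criterion_id])
    ))
    return TornadoResult(delta=float(delta), base_v_a=base_a.total,
                         base_v_b=base_b.total, entries=ranked)


# ---------------------------------------------------------------------------
# Inverse weight calibration
# ---------------------------------------------------------------------------

#: Strictness margin for '>' ordering constraints.
STRICT_MARGIN = 1e-9

_RELATIONS = ("gt", "ge", "eq")


@dataclass(frozen=True)
class OrderingConstraint:
    """Qualitative relation between two criteria's raw weights."""

    relation: str  # gt | ge | eq
    left: str
    right: str

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValidationError(
                f"unknown constraint relation {self.relation!r}; expected {_RELATIONS}"
            )

    def satisfied(self, raw: Mapping[str, float]) -> bool:
        a, b = raw[self.left], raw[self.right]
        if self.relation == "gt":
            return a - b >= STRICT_MARGIN
        if self.relation == "ge":
            return a >= b
        return a == b

    def __str__(self) -> str:
        symbol = {"gt": ">", "ge": ">=", "eq": "="}[self.relation]
        return f"{self.left} {symbol} {self.right}"


@dataclass(frozen=True)
class CalibrationProblem:
    """Find raw weights in ``bounds`` whose model values, rounded to
    ``precision`` decimals (half-up), equal the per-intervention targets while
    satisfying every ordering constraint."""

    framework: FrameworkDefinition
    summaries: Mapping[str, ScoreSummary]
    targets: Mapping[str, float]           # intervention -> target V (rounded scale)
    constraints: Sequence[OrderingConstraint] = ()
    bounds: tuple[float, float] = (1.0, 5.0)
    precision: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.bounds[0] <= self.bounds[1]):
            raise ValidationError(f"raw-weight bounds must be positive, got {self.bounds}")
        if set(self.targets) - set(self.summaries):
            raise ValidationError("targets name interventions without score summaries")
        cids = set(self.framework.criterion_ids)
        for con in self.constraints:
            if con.left not in cids or con.right not in cids:
                raise ValidationError(f"constraint {con} references unknown criteria")
        _validate_constraint_system(self.constraints)
        object.__setattr__(self, "summaries", dict(self.summaries))
        object.__setattr__(self, "targets", dict(self.targets))
        object.__setattr__(self, "constraints", tuple(self.constraints))


@dataclass(frozen=True)
class CalibrationResult:
    feasible: bool
    weights: WeightVector | None
    achieved: Mapping[str, float]          # full-precision V per intervention
    achieved_rounded: Mapping[str, float]
    targets: Mapping[str, float]
    message: str

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "weights": dict(self.weights.raw) if self.weights else None,
            "achieved": dict(self.achieved),
            "achieved_rounded": dict(self.achieved_rounded),
            "targets": dict(self.targets),
            "message": self.message,
        }


def _validate_constraint_system(constraints: Sequence[OrderingConstraint]) -> None:
    """Reject internally contradictory systems: a 'gt' cycle through the
    equality-merged criterion graph."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for con in constraints:
        if con.relation == "eq":
            parent[find(con.left)] = find(con.right)
    edges: set[tuple[str, str, bool]] = set()
    for con in constraints:
        if con.relation == "eq":
            continue
        a, b = find(con.left), find(con.right)
        strict = con.relation == "gt"
        if a == b and strict:
            raise ValidationError(f"contradictory constraints: {con} with equal weights")
        edges.add((a, b, strict))
    # detect cycles containing a strict edge (allows a >= b and b >= a)
    adjacency: dict[str, list[tuple[str, bool]]] = {}
    for a, b, strict in edges:
        adjacency.setdefault(a, []).append((b, strict))
    for start in list(adjacency):
        stack = [(start, False)]
        seen: set[str] = set()
        while stack:
            node, any_strict = stack.pop()
            for nxt, strict in adjacency.get(node, ()):
                s = any_strict or strict
                if nxt == start and s:
                    raise ValidationError(
                        "contradictory ordering constraints (strict cycle detected)"
                    )
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, s))


def _merge_classes(framework: FrameworkDefinition,
                   constraints: Sequence[OrderingConstraint]
                   ) -> tuple[list[tuple[str, ...]], dict[str, int]]:
    """Union criteria linked by 'eq' constraints into shared free variables."""
    parent: dict[str, str] = {cid: cid for cid in framework.criterion_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for con in constraints:
        if con.relation == "eq":
            parent[find(con.left)] = find(con.right)
    groups: dict[str, list[str]] = {}
    for cid in framework.criterion_ids:
        groups.setdefault(find(cid), []).append(cid)
    classes = [tuple(members) for members in groups.values()]
    index = {cid: k for k, cls in enumerate(classes) for cid in cls}
    return classes, index


def _vectorized_round_half_up(x: np.ndarray, ndigits: int) -> np.ndarray:
    scale = 10.0 ** ndigits
    return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale


def calibrate_weights(problem: CalibrationProblem) -> CalibrationResult:
    """Deterministic inverse search for a feasible weight vector.

    Stage 1 scans a coarse grid over the equality-merged free weights within
    the bounds, keeping constraint-satisfying vectors; stage 2 refines the
    best grid candidate by bounded least squares on the residual to the
    (unrounded) targets, subject to the ordering constraints. Success means
    the rounded value pair equals the targets exactly; otherwise an
    infeasibility report carries the closest achieved pair.
    """
    fw = problem.framework
    interventions = list(problem.targets)
    for name in interventions:
        problem.summaries[name].validate_against(fw)
    # target sanity: V is bounded by max |S_x| <= 1
    for name, t in problem.targets.items():
        if not (-1.0 <= t <= 1.0):
            return CalibrationResult(
                feasible=False, weights=None, achieved={}, achieved_rounded={},
                targets=dict(problem.targets),
                message=f"target {t} for {name!r} is outside the attainable range [-1, 1]",
            )

    classes, index = _merge_classes(fw, problem.constraints)
    k = len(classes)
    cids = fw.criterion_ids
    # normalized score matrix: interventions x criteria
    s = np.array([
        [problem.summaries[name].means[cid] / 5.0 for cid in cids]
        for name in interventions
    ])
    # expansion matrix: criteria x classes
    expand = np.zeros((len(cids), k))
    for j, cid in enumerate(cids):
        expand[j, index[cid]] = 1.0
    targets = np.array([problem.targets[name] for name in interventions])

    lo, hi = problem.bounds
    grid_values = np.asarray(_grid_levels(lo, hi, k), dtype=float)
    mesh = np.meshgrid(*([grid_values] * k), indexing="ij")
    candidates = np.stack([m.ravel() for m in mesh], axis=-1)   # n x k
    mask = np.ones(len(candidates), dtype=bool)
    for con in problem.constraints:
        if con.relation == "eq":
            continue  # folded into the shared free variable
        a = candidates[:, index[con.left]]
        b = candidates[:, index[con.right]]
        mask &= (a - b >= STRICT_MARGIN) if con.relation == "gt" else (a >= b)
    feasible = candidates[mask]
    if feasible.size == 0:
        return CalibrationResult(
            feasible=False, weights=None, achieved={}, achieved_rounded={},
            targets=dict(problem.targets),
            message="no grid point satisfies the ordering constraints",
        )
    class_size = expand.sum(axis=0)                   # criteria per class
    score_by_class = expand.T @ s.T                   # k x interventions
    values = (feasible @ score_by_class) / (feasible @ class_size)[:, None]
    rounded = _vectorized_round_half_up(values, problem.precision)
    resid = np.sum((values - targets) ** 2, axis=1)
    hits = np.all(np.abs(rounded - targets) < 10.0 ** (-problem.precision - 6), axis=1)

    if hits.any():
        # among exact hits, prefer the one closest to the unrounded targets
        hit_idx = np.flatnonzero(hits)
        start = feasible[hit_idx[np.argmin(resid[hit_idx])]]
    else:
        start = feasible[int(np.argmin(resid))]

    refined = _refine(start, expand, s, targets, problem, classes, cids)
    candidates_final = [refined, start] if refined is not None else [start]

    best = None
    for cand in candidates_final:
        raw_full = cand @ expand.T if cand.ndim == 1 else cand
        raw = {cid: float(raw_full[j]) for j, cid in enumerate(cids)}
        if not all(con.satisfied(raw) for con in problem.constraints):
            continue
        if not all(lo <= w <= hi for w in raw.values()):
            continue
        wv = WeightVector(raw)
        achieved = {
            name: compute_value(wv, problem.summaries[name], fw).total
            for name in interventions
        }
        achieved_rounded = {
            name: round_half_up(v, problem.precision) for name, v in achieved.items()
        }
        ok = all(
            math.isclose(achieved_rounded[name], problem.targets[name], abs_tol=1e-12)
            for name in interventions
        )
        err = sum((achieved[name] - problem.targets[name]) ** 2 for name in interventions)
        entry = (ok, -err, wv, achieved, achieved_rounded)
        if ok:
            best = entry
            break
        if best is None or entry[1] > best[1]:
            best = entry

    if best is None:  # refinement left the feasible region and no fallback survived
        return CalibrationResult(
            feasible=False, weights=None, achieved={}, achieved_rounded={},
            targets=dict(problem.targets),
            message="search produced no constraint-satisfying candidate",
        )
    ok, _, wv, achieved, achieved_rounded = best
    if ok:
        return CalibrationResult(
            feasible=True, weights=wv, achieved=achieved,
            achieved_rounded=achieved_rounded, targets=dict(problem.targets),
            message="calibrated weight vector found",
        )
    return CalibrationResult(
        feasible=False, weights=wv, achieved=achieved,
        achieved_rounded=achieved_rounded, targets=dict(problem.targets),
        message=(
            "no constraint-satisfying weight vector rounds to the targets; "
            "reporting the closest achieved pair"
        ),
    )


def _grid_levels(lo: float, hi: float, k: int, budget: int = 2_000_000) -> list[float]:
    """Deterministic coarse grid levels per free weight, sized to the budget."""
    if lo == hi:
        return [lo]
    for levels in (5, 3, 2):
        if levels ** k <= budget:
            return list(np.linspace(lo, hi, levels))
    return [lo, hi]


def _refine(start: np.ndarray, expand: np.ndarray, s: np.ndarray,
            targets: np.ndarray, problem: CalibrationProblem,
            classes: Sequence[tuple[str, ...]], cids: Sequence[str],
            ) -> np.ndarray | None:
    """Bounded least-squares polish of the grid candidate (SLSQP on the
    squared residual to the unrounded targets, ordering constraints kept)."""
    class_of = {cid: k for k, cls in enumerate(classes) for cid in cls}

    def values(x: np.ndarray) -> np.ndarray:
        w = x @ expand.T
        return (s @ w) / w.sum()

    def objective(x: np.ndarray) -> float:
        return float(np.sum((values(x) - targets) ** 2))

    cons = []
    for con in problem.constraints:
        if con.relation == "eq":
            continue  # folded into the shared free variable
        i, j = class_of[con.left], class_of[con.right]
        margin = 1e-6 if con.relation == "gt" else 0.0
        cons.append({
            "type": "ineq",
            "fun": (lambda x, i=i, j=j, margin=margin: x[i] - x[j] - margin),
        })
    try:
        res = optimize.minimize(
            objective, start, method="SLSQP",
            bounds=[problem.bounds] * len(start),
            constraints=cons,
            options={"maxiter": 200, "ftol": 1e-14},
        )
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    x = np.clip(res.x, problem.bounds[0], problem.bounds[1])
    return x
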