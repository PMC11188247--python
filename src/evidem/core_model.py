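"""EVIDEM core value model.

The framework is a fixed hierarchy of value *domains*, each containing one
or more *criteria*. Every criterion is scored on one of two integer scales:

* **absolute** criteria (0..5) judge the intervention against a fixed anchor
  (e.g. disease severity: very severe -> not severe);
* **relative** criteria (-5..5) judge it against a comparator intervention,
  with 0 meaning "no difference".

Given a weight vector :math:`W` and per-criterion mean scores, the total
value of an intervention is the additive linear aggregate

.. math::

    V = \\sum_x V_x = \\sum_x \\frac{W_x}{\\sum_n W_n} \\, S_x,
    \\qquad S_x = \\text{score}_x / 5,

so each criterion contributes its normalized weight times its normalized
score, and :math:`V` lies in [-1, 1] (in [0, 1] when all criteria are
absolute). The sum runs over the framework's criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import StructuralError, ValidationError

__all__ = [
    "ScoringScale",
    "Criterion",
    "Domain",
    "FrameworkDefinition",
    "WeightVector",
    "ScoreSummary",
    "ValueBreakdown",
    "ComparisonResult",
    "normalize_score",
    "compute_value",
    "compare_interventions",
    "core_framework",
    "round_half_up",
]

#: Divisor turning a raw scale score into a normalized score S_x = score / 5.
SCORE_DIVISOR = 5.0

_SCALE_BOUNDS = {"absolute": (0, 5), "relative": (-5, 5)}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    Display values in reports use this convention; internal arithmetic is
    never rounded.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoringScale:
    """Integer scoring scale of a criterion.

    kind='absolute' spans 0..5, kind='relative' spans -5..5.
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _SCALE_BOUNDS:
            raise ValidationError(
                f"unknown scale kind {self.kind!r}; expected 'absolute' or 'relative'"
            )

    @property
    def lower(self) -> int:
        return _SCALE_BOUNDS[self.kind][0]

    @property
    def upper(self) -> int:
        return _SCALE_BOUNDS[self.kind][1]

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class Criterion:
    id: str
    name: str
    domain_id: str
    scale: ScoringScale
    indicators: tuple[str, ...] = ()


@dataclass(frozen=True)
class Domain:
    id: str
    name: str


@dataclass(frozen=True)
class FrameworkDefinition:
    """Ordered domains and criteria; order is stable and used for reporting."""

    domains: tuple[Domain, ...]
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        domain_ids = [d.id for d in self.domains]
        if len(set(domain_ids)) != len(domain_ids):
            raise ValidationError("duplicate domain ids in framework")
        crit_ids = [c.id for c in self.criteria]
        if len(set(crit_ids)) != len(crit_ids):
            raise ValidationError("duplicate criterion ids in framework")
        for c in self.criteria:
            if c.domain_id not in domain_ids:
                raise ValidationError(
                    f"criterion {c.id!r} refers to unknown domain {c.domain_id!r}"
                )
        for d in self.domains:
            if not any(c.domain_id == d.id for c in self.criteria):
                raise ValidationError(f"domain {d.id!r} contains no criteria")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.domains)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise StructuralError(f"unknown criterion {criterion_id!r}")

    def criteria_in_domain(self, domain_id: str) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.domain_id == domain_id)

    def domain_name(self, domain_id: str) -> str:
        for d in self.domains:
            if d.id == domain_id:
                return d.name
        raise StructuralError(f"unknown domain {domain_id!r}")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "domains": [{"id": d.id, "name": d.name} for d in self.domains],
            "criteria": [
                {
                    "id": c.id,
                    "name": c.name,
                    "domain": c.domain_id,
                    "scale": c.scale.kind,
                    "indicators": list(c.indicators),
                }
                for c in self.criteria
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FrameworkDefinition":
        try:
            domains = tuple(Domain(d["id"], d["name"]) for d in data["domains"])
            criteria = tuple(
                Criterion(
                    id=c["id"],
                    name=c["name"],
                    domain_id=c["domain"],
                    scale=ScoringScale(c["scale"]),
                    indicators=tuple(c.get("indicators", ())),
                )
                for c in data["criteria"]
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed framework definition: {exc}") from exc
        return cls(domains=domains, criteria=criteria)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrameworkDefinition":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(data)


def core_framework() -> FrameworkDefinition:
    """The bundled 5-domain / 13-criterion core model used for the
    vonoprazan-vs-tegoprazan appraisal (and as the package default)."""
    ref = resources.files("evidem").joinpath("data/framework_core.yaml")
    return FrameworkDefinition.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class WeightVector:
    """Raw per-criterion weights W_x > 0 and their sum-to-one normalization."""

    raw: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.raw:
            raise ValidationError("weight vector is empty")
        for cid, w in self.raw.items():
            if not (w > 0):
                raise ValidationError(
                    f"raw weight for criterion {cid!r} must be positive, got {w}"
                )
        object.__setattr__(self, "raw", dict(self.raw))

    @property
    def total(self) -> float:
        return float(sum(self.raw.values()))

    @property
    def normalized(self) -> dict[str, float]:
        t = self.total
        return {cid: w / t for cid, w in self.raw.items()}

    def align(self, framework: FrameworkDefinition) -> None:
        """Raise if the weight keys do not match the framework's criteria."""
        want, have = set(framework.criterion_ids), set(self.raw)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise StructuralError(
                f"weight vector does not match framework: missing {missing}, extra {extra}"
            )

    def scaled(self, factor: float) -> "WeightVector":
        if not (factor > 0):
            raise ValidationError("scale factor must be positive")
        return WeightVector({cid: w * factor for cid, w in self.raw.items()})

    @classmethod
    def uniform(cls, framework: FrameworkDefinition, value: float = 1.0) -> "WeightVector":
        return cls({cid: value for cid in framework.criterion_ids})


@dataclass(frozen=True)
class ScoreSummary:
    """Per-intervention panel score summary: mean and SD per criterion,
    on the criterion's own scale."""

    intervention: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    n_experts: int | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", dict(self.means))
        object.__setattr__(self, "sds", dict(self.sds))
        object.__setattr__(self, "annotations", dict(self.annotations))
        if set(self.means) != set(self.sds):
            raise StructuralError(
                f"{self.intervention}: means and sds cover different criteria"
            )
        for cid, sd in self.sds.items():
            if sd < 0:
                raise ValidationError(
                    f"{self.intervention}/{cid}: sd must be >= 0, got {sd}"
                )

    def validate_against(self, framework: FrameworkDefinition) -> None:
        want, have = set(framework.criterion_ids), set(self.means)
        if want != have:
            raise StructuralError(
                f"score summary for {self.intervention!r} does not cover the framework: "
                f"missing {sorted(want - have)}, extra {sorted(have - want)}"
            )
        for c in framework.criteria:
            m = self.means[c.id]
            if not c.scale.contains(m):
                raise ValidationError(
                    f"{self.intervention}/{c.id}: mean {m} outside scale "
                    f"[{c.scale.lower}, {c.scale.upper}]"
                )

    def with_score(self, criterion_id: str, mean: float, sd: float,
                   annotation: str | None = None) -> "ScoreSummary":
        means = {**self.means, criterion_id: mean}
        sds = {**self.sds, criterion_id: sd}
        annotations = dict(self.annotations)
        if annotation is not None:
            annotations[criterion_id] = annotation
        return ScoreSummary(self.intervention, means, sds, self.n_experts, annotations)


@dataclass(frozen=True)
class ValueBreakdown:
    """Decomposition of the additive value: per-criterion contributions V_x,
    per-domain subtotals, and the total V. Criterion/domain key order follows
    the framework."""

    intervention: str
    normalized_scores: Mapping[str, float]
    contributions: Mapping[str, float]
    domain_subtotals: Mapping[str, float]
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "normalized_scores", dict(self.normalized_scores))
        object.__setattr__(self, "contributions", dict(self.contributions))
        object.__setattr__(self, "domain_subtotals", dict(self.domain_subtotals))

    @property
    def total_display(self) -> float:
        """Total rounded half-up to 2 decimals, the report convention."""
        return round_half_up(self.total, 2)

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "normalized_scores": dict(self.normalized_scores),
            "contributions": dict(self.contributions),
            "domain_subtotals": dict(self.domain_subtotals),
            "total": self.total,
            "total_display": self.total_display,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_markdown(self, framework: FrameworkDefinition) -> str:
        lines = [
            f"## Value breakdown: {self.intervention}",
            "",
            "| Domain | Criterion | S_x | V_x |",
            "|---|---|---:|---:|",
        ]
        for c in framework.criteria:
            lines.append(
                f"| {framework.domain_name(c.domain_id)} | {c.name} "
                f"| {self.normalized_scores[c.id]:.4f} "
                f"| {self.contributions[c.id]:.4f} |"
            )
        lines.append("")
        lines.append("| Domain | Subtotal |")
        lines.append("|---|---:|")
        for d in framework.domains:
            lines.append(f"| {d.name} | {self.domain_subtotals[d.id]:.4f} |")
        lines.append("")
        lines.append(f"**Total V = {self.total_display:.2f}** (full precision {self.total:.6f})")
        return "\n".join(lines) + "\n"


def normalize_score(mean_score: float, scale: ScoringScale,
                    criterion_id: str | None = None) -> float:
    """Normalize a mean score to S_x = score / 5 (relative scales may be negative)."""
    if not scale.contains(mean_score):
        label = f" for criterion {criterion_id!r}" if criterion_id else ""
        raise ValidationError(
            f"score {mean_score}{label} outside scale bounds "
            f"[{scale.lower}, {scale.upper}]"
        )
    return mean_score / SCORE_DIVISOR


def compute_value(weights: WeightVector, scores: ScoreSummary,
                  framework: FrameworkDefinition) -> ValueBreakdown:
    """Evaluate the additive linear value model.

    V_x = (W_x / sum W) * S_x per criterion; domain subtotals and the total
    are exact sums of the V_x. All arithmetic is full precision; rounding is
    applied only at display time.
    """
    weights.align(framework)
    scores.validate_against(framework)
    norm_w = weights.normalized
    normalized_scores: dict[str, float] = {}
    contributions: dict[str, float] = {}
    for c in framework.criteria:
        s = normalize_score(scores.means[c.id], c.scale, c.id)
        normalized_scores[c.id] = s
        contributions[c.id] = norm_w[c.id] * s
    domain_subtotals = {
        d.id: sum(contributions[c.id] for c in framework.criteria_in_domain(d.id))
        for d in framework.domains
    }
    total = sum(contributions[c.id] for c in framework.criteria)
    return ValueBreakdown(
        intervention=scores.intervention,
        normalized_scores=normalized_scores,
        contributions=contributions,
        domain_subtotals=domain_subtotals,
        total=total,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Per-criterion and per-domain value differences a - b, with domains
    ranked by |difference| (framework order breaks ties)."""

    intervention_a: str
    intervention_b: str
    criterion_deltas: Mapping[str, float]
    domain_deltas: Mapping[str, float]
    ranked_domains: tuple[str, ...]
    total_delta: float

    def to_dict(self) -> dict:
        return {
            "intervention_a": self.intervention_a,
            "intervention_b": self.intervention_b,
            "criterion_deltas": dict(self.criterion_deltas),
            "domain_deltas": dict(self.domain_deltas),
            "ranked_domains": list(self.ranked_domains),
            "total_delta": self.total_delta,
        }


def compare_interventions(a: ValueBreakdown, b: ValueBreakdown) -> ComparisonResult:
    """Compare two breakdowns computed on the same framework and weights.

    Domains are ranked by absolute value-contribution difference, descending;
    ties keep the breakdown's (i.e. the framework's) domain order.
    """
    if tuple(a.contributions) != tuple(b.contributions) or \
            tuple(a.domain_subtotals) != tuple(b.domain_subtotals):
        raise StructuralError(
            "cannot compare breakdowns computed on different frameworks"
        )
    criterion_deltas = {
        cid: a.contributions[cid] - b.contributions[cid] for cid in a.contributions
    }
    domain_deltas = {
        did: a.domain_subtotals[did] - b.domain_subtotals[did]
        for did in a.domain_subtotals
    }
    order = list(a.domain_subtotals)
    ranked = tuple(
        sorted(order, key=lambda did: (-abs(domain_deltas[did]), order.index(did)))
    )
    return ComparisonResult(
        intervention_a=a.intervention,
        intervention_b=b.intervention,
        criterion_deltas=criterion_deltas,
        domain_deltas=domain_deltas,
        ranked_domains=ranked,
        total_delta=a.total - b.total,
    )
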