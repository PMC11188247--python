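"""Expert-panel criterion scoring and aggregation.

Each panel member scores every criterion for every intervention on the
criterion's integer scale. Panel summaries report the arithmetic mean and the
sample standard deviation (n-1 denominator) per criterion.

Two panel policies are enforced here:

* **relative-scoring consensus rule** — when the evidence shows no significant
  difference between the two interventions relative to the comparator, their
  mean scores on that relative criterion may not differ by more than 1 point;
* **missing-evidence policy** — a criterion with no retrieved evidence for an
  intervention is scored 0 (SD 0) and annotated 'no-evidence'; its weight
  remains in the weight sum (no renormalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import FrameworkDefinition, ScoreSummary
from .errors import StructuralError, ValidationError

__all__ = [
    "ExpertScoreSheet",
    "SignificanceMap",
    "EvidenceEntry",
    "RuleViolation",
    "aggregate_scores",
    "validate_relative_rule",
    "validate_relative_rule_per_expert",
    "apply_missing_evidence_policy",
    "NO_SIGNIFICANT_DIFFERENCE",
    "DISCERNIBLE_DISTINCTION",
    "MAX_MEAN_DIFFERENCE",
    "read_score_summaries",
    "write_score_summaries",
]

NO_SIGNIFICANT_DIFFERENCE = "no_significant_difference"
DISCERNIBLE_DISTINCTION = "discernible_distinction"

#: Consensus cap on the score difference between interventions whose evidence
#: shows no significant difference relative to the comparator.
MAX_MEAN_DIFFERENCE = 1.0


@dataclass(frozen=True)
class ExpertScoreSheet:
    """Raw integer scores: expert -> intervention -> criterion -> score."""

    scores: Mapping[str, Mapping[str, Mapping[str, int]]]

    def __post_init__(self) -> None:
        if not self.scores:
            raise StructuralError("score sheet has no experts")
        clean = {
            e: {i: dict(crits) for i, crits in byint.items()}
            for e, byint in self.scores.items()
        }
        object.__setattr__(self, "scores", clean)

    @property
    def experts(self) -> tuple[str, ...]:
        return tuple(self.scores)

    @property
    def interventions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for byint in self.scores.values():
            for i in byint:
                seen.setdefault(i)
        return tuple(seen)

    def validate_against(self, framework: FrameworkDefinition) -> None:
        """Check score integrality and scale bounds for every entry, and that
        every expert covers every intervention/criterion pair present."""
        pairs = {
            (i, c)
            for byint in self.scores.values()
            for i, crits in byint.items()
            for c in crits
        }
        for expert, byint in self.scores.items():
            have = {(i, c) for i, crits in byint.items() for c in crits}
            if have != pairs:
                raise StructuralError(
                    f"expert {expert!r} did not score every criterion-intervention pair"
                )
            for intervention, crits in byint.items():
                for cid, s in crits.items():
                    crit = framework.criterion(cid)
                    if isinstance(s, bool) or float(s) != int(s):
                        raise ValidationError(
                            f"expert {expert!r}, {intervention}/{cid}: "
                            f"score {s!r} is not an integer"
                        )
                    if not crit.scale.contains(int(s)):
                        raise ValidationError(
                            f"expert {expert!r}, {intervention}/{cid}: score {s} "
                            f"outside scale [{crit.scale.lower}, {crit.scale.upper}]"
                        )

    # -- CSV interface: expert_id, criterion_id, intervention, score ----

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"expert_id": e, "criterion_id": c, "intervention": i, "score": s}
            for e, byint in self.scores.items()
            for i, crits in byint.items()
            for c, s in crits.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpertScoreSheet":
        df = pd.read_csv(path, comment="#")
        required = {"expert_id", "criterion_id", "intervention", "score"}
        if not required.issubset(df.columns):
            raise ValidationError(f"score sheet CSV must have columns {sorted(required)}")
        scores: dict[str, dict[str, dict[str, int]]] = {}
        for rec in df.itertuples(index=False):
            if float(rec.score) != int(rec.score):
                raise ValidationError(
                    f"expert {rec.expert_id!r}, {rec.intervention}/{rec.criterion_id}: "
                    f"score {rec.score} is not an integer"
                )
            scores.setdefault(str(rec.expert_id), {}) \
                .setdefault(str(rec.intervention), {})[str(rec.criterion_id)] = int(rec.score)
        return cls(scores)


def aggregate_scores(sheet: ExpertScoreSheet,
                     framework: FrameworkDefinition) -> dict[str, ScoreSummary]:
    """Aggregate raw expert scores to per-intervention mean +/- SD summaries.

    The SD is the sample standard deviation (n-1 denominator); a single-expert
    panel yields SD 0 with a warning. Values are stored at full precision;
    1-decimal rounding is a display convention only.
    """
    sheet.validate_against(framework)
    n = len(sheet.experts)
    if n == 1:
        warnings.warn(
            "panel has a single expert: SDs are reported as 0", stacklevel=2
        )
    summaries: dict[str, ScoreSummary] = {}
    for intervention in sheet.interventions:
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        cids = sheet.scores[sheet.experts[0]][intervention]
        for cid in cids:
            vals = np.array(
                [sheet.scores[e][intervention][cid] for e in sheet.experts],
                dtype=float,
            )
            means[cid] = float(vals.mean())
            sds[cid] = float(vals.std(ddof=1)) if n > 1 else 0.0
        summaries[intervention] = ScoreSummary(
            intervention=intervention, means=means, sds=sds, n_experts=n
        )
    return summaries


@dataclass(frozen=True)
class SignificanceMap:
    """Evidence verdict per relative criterion: does the comparator evidence
    show a discernible distinction between the two interventions?"""

    verdicts: Mapping[str, str]

    def __post_init__(self) -> None:
        for cid, v in self.verdicts.items():
            if v not in (NO_SIGNIFICANT_DIFFERENCE, DISCERNIBLE_DISTINCTION):
                raise ValidationError(
                    f"criterion {cid!r}: unknown significance verdict {v!r}"
                )
        object.__setattr__(self, "verdicts", dict(self.verdicts))

    def validate_against(self, framework: FrameworkDefinition) -> None:
        for cid in self.verdicts:
            crit = framework.criterion(cid)  # raises on unknown criterion
            if crit.scale.kind != "relative":
                raise ValidationError(
                    f"significance verdict given for non-relative criterion {cid!r}"
                )


@dataclass(frozen=True)
class RuleViolation:
    criterion_id: str
    mean_a: float
    mean_b: float
    difference: float
    limit: float
    expert_id: str | None = None

    def __str__(self) -> str:
        who = f" (expert {self.expert_id})" if self.expert_id else ""
        return (
            f"{self.criterion_id}{who}: |{self.mean_a} - {self.mean_b}| = "
            f"{self.difference:g} exceeds the {self.limit:g}-point consensus cap"
        )


def validate_relative_rule(summary_a: ScoreSummary, summary_b: ScoreSummary,
                           sig: SignificanceMap,
                           framework: FrameworkDefinition,
                           limit: float = MAX_MEAN_DIFFERENCE) -> list[RuleViolation]:
    """Check the consensus cap on panel means.

    For each relative criterion whose evidence shows no significant
    difference, flag it when |mean_a - mean_b| strictly exceeds ``limit``.
    An empty list means the summaries comply.
    """
    sig.validate_against(framework)
    violations: list[RuleViolation] = []
    for cid, verdict in sig.verdicts.items():
        if verdict != NO_SIGNIFICANT_DIFFERENCE:
            continue
        ma, mb = summary_a.means[cid], summary_b.means[cid]
        diff = abs(ma - mb)
        if diff > limit:
            violations.append(RuleViolation(cid, ma, mb, diff, limit))
    return violations


def validate_relative_rule_per_expert(sheet: ExpertScoreSheet,
                                      intervention_a: str, intervention_b: str,
                                      sig: SignificanceMap,
                                      framework: FrameworkDefinition,
                                      limit: float = MAX_MEAN_DIFFERENCE,
                                      ) -> list[RuleViolation]:
    """Strict mode: enforce the consensus cap on every individual expert's
    score pair instead of the panel means."""
    sig.validate_against(framework)
    violations: list[RuleViolation] = []
    for expert in sheet.experts:
        for cid, verdict in sig.verdicts.items():
            if verdict != NO_SIGNIFICANT_DIFFERENCE:
                continue
            sa = sheet.scores[expert][intervention_a][cid]
            sb = sheet.scores[expert][intervention_b][cid]
            diff = abs(sa - sb)
            if diff > limit:
                violations.append(
                    RuleViolation(cid, sa, sb, diff, limit, expert_id=expert)
                )
    return violations


@dataclass(frozen=True)
class EvidenceEntry:
    """One evidence-matrix entry: a narrative finding for a criterion, with a
    quality flag. quality='missing' marks that no evidence was retrieved."""

    criterion_id: str
    narrative: str
    quality: str
    intervention: str | None = None

    _QUALITIES = ("high", "moderate", "low", "missing")

    def __post_init__(self) -> None:
        if self.quality not in self._QUALITIES:
            raise ValidationError(
                f"criterion {self.criterion_id!r}: unknown quality flag "
                f"{self.quality!r}; expected one of {self._QUALITIES}"
            )


NO_EVIDENCE_ANNOTATION = "no-evidence"


def apply_missing_evidence_policy(summaries: Mapping[str, ScoreSummary],
                                  evidence: Iterable[EvidenceEntry],
                                  ) -> dict[str, ScoreSummary]:
    """Zero out criteria with 'missing' evidence.

    An entry with quality='missing' and a named intervention zeroes that
    intervention's score for the criterion; with no intervention named, every
    intervention is zeroed. Weights are untouched: the criterion stays in the
    weight sum. Quality flags other than 'missing' never modify scores.
    """
    result = dict(summaries)
    for entry in evidence:
        if entry.quality != "missing":
            continue
        targets = (
            [entry.intervention] if entry.intervention is not None else list(result)
        )
        for name in targets:
            if name not in result:
                raise StructuralError(
                    f"missing-evidence entry names unknown intervention {name!r}"
                )
            result[name] = result[name].with_score(
                entry.criterion_id, 0.0, 0.0, annotation=NO_EVIDENCE_ANNOTATION
            )
    return result


# ---------------------------------------------------------------------------
# Score-summary CSV interface
# (columns: intervention, criterion_id, mean, sd, no_evidence)
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    text = f"{x:.10g}"
    return text


def write_score_summaries(summaries: Mapping[str, ScoreSummary],
                          path: str | Path) -> None:
    """Write summaries in the canonical CSV form (deterministic bytes)."""
    lines = ["intervention,criterion_id,mean,sd,no_evidence"]
    for name, summary in summaries.items():
        for cid in summary.means:
            flag = "yes" if summary.annotations.get(cid) == NO_EVIDENCE_ANNOTATION else "no"
            lines.append(
                f"{name},{cid},{_format_number(summary.means[cid])},"
                f"{_format_number(summary.sds[cid])},{flag}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_score_summaries(path: str | Path,
                         n_experts: int | None = None) -> dict[str, ScoreSummary]:
    """Read per-intervention summaries from CSV ('#' lines are comments)."""
    df = pd.read_csv(path, comment="#")
    required = {"intervention", "criterion_id", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValidationError(f"score summary CSV must have columns {sorted(required)}")
    summaries: dict[str, ScoreSummary] = {}
    for name, group in df.groupby("intervention", sort=False):
        means = dict(zip(group["criterion_id"].astype(str), group["mean"].astype(float)))
        sds = dict(zip(group["criterion_id"].astype(str), group["sd"].astype(float)))
        annotations = {}
        if "no_evidence" in group.columns:
            annotations = {
                str(cid): NO_EVIDENCE_ANNOTATION
                for cid, flag in zip(group["criterion_id"], group["no_evidence"])
                if str(flag).lower() in ("yes", "true", "1")
            }
        summaries[str(name)] = ScoreSummary(
            intervention=str(name), means=means, sds=sds,
            n_experts=n_experts, annotations=annotations,
        )
    return summaries
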