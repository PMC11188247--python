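"""Synthetic expert panels and bundled reference fixtures.

The generator emulates the statistical structure of a hospital PTC appraisal
panel: ``n_experts`` members (default 14, two from each of seven hospital
disciplines) independently emit

* an integer 1..5 impact rating per criterion (the weighting tool), and
* an integer criterion score per intervention on the criterion's scale,

by sampling a normal at a latent true mean, rounding to the nearest integer
and clipping to the bounds. Round-then-clip introduces a small, bounded
discretization bias near the scale edges; the documented tolerance for
parameter recovery accounts for it.

The module also ships the published panel-score fixture for the
vonoprazan/tegoprazan GERD appraisal and the affordability arithmetic used
in its economic criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping

import numpy as np

from .core_model import FrameworkDefinition, ScoreSummary, core_framework
from .errors import ValidationError
from .panel_scoring import ExpertScoreSheet, read_score_summaries
from .weight_elicitation import RatingSheet

__all__ = [
    "PanelProfile",
    "generate_panel",
    "default_profile",
    "reference_panel_scores",
    "affordability_share",
]

DEFAULT_N_EXPERTS = 14
DEFAULT_RATING_SD = 0.8


@dataclass(frozen=True)
class PanelProfile:
    """Latent panel structure the generator samples from.

    ``rating_means`` are the true per-criterion weight-rating means on the
    1..5 tool; ``score_means``/``score_sds`` give the true score distribution
    per intervention and criterion on the criterion's own scale.
    """

    framework: FrameworkDefinition
    rating_means: Mapping[str, float]
    score_means: Mapping[str, Mapping[str, float]]   # intervention -> criterion -> mean
    score_sds: Mapping[str, Mapping[str, float]]
    n_experts: int = DEFAULT_N_EXPERTS
    rating_sd: float = DEFAULT_RATING_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValidationError(f"n_experts must be >= 1, got {self.n_experts}")
        if self.rating_sd < 0:
            raise ValidationError(f"rating_sd must be >= 0, got {self.rating_sd}")
        cids = set(self.framework.criterion_ids)
        if set(self.rating_means) != cids:
            raise ValidationError("rating_means must cover exactly the framework criteria")
        for cid, m in self.rating_means.items():
            if not (1.0 <= m <= 5.0):
                raise ValidationError(f"rating mean for {cid!r} outside [1, 5]: {m}")
        if set(self.score_means) != set(self.score_sds):
            raise ValidationError("score_means and score_sds name different interventions")
        for name in self.score_means:
            if set(self.score_means[name]) != cids or set(self.score_sds[name]) != cids:
                raise ValidationError(
                    f"score profile for {name!r} must cover exactly the framework criteria"
                )
            for c in self.framework.criteria:
                m = self.score_means[name][c.id]
                if not c.scale.contains(m):
                    raise ValidationError(
                        f"{name}/{c.id}: true score mean {m} outside scale bounds"
                    )
                if self.score_sds[name][c.id] < 0:
                    raise ValidationError(f"{name}/{c.id}: sd must be >= 0")
        object.__setattr__(self, "rating_means", dict(self.rating_means))
        object.__setattr__(
            self, "score_means", {k: dict(v) for k, v in self.score_means.items()}
        )
        object.__setattr__(
            self, "score_sds", {k: dict(v) for k, v in self.score_sds.items()}
        )


def _discretize(draws: np.ndarray, lower: float, upper: float) -> np.ndarray:
    return np.clip(np.rint(draws), lower, upper).astype(int)


def generate_panel(profile: PanelProfile) -> tuple[RatingSheet, ExpertScoreSheet]:
    """Sample a full panel: one rating sheet and one score sheet.

    Draw order is fixed (ratings first, then scores, expert-major), so the
    same profile and seed always reproduce identical sheets.
    """
    fw = profile.framework
    rng = np.random.default_rng(profile.seed)
    experts = [f"e{i + 1:02d}" for i in range(profile.n_experts)]
    cids = fw.criterion_ids

    rating_mu = np.array([profile.rating_means[c] for c in cids])
    rating_draws = rng.normal(rating_mu, profile.rating_sd,
                              size=(profile.n_experts, len(cids)))
    rating_ints = _discretize(rating_draws, 1, 5)
    ratings = {
        e: {cid: int(rating_ints[i, j]) for j, cid in enumerate(cids)}
        for i, e in enumerate(experts)
    }

    scores: dict[str, dict[str, dict[str, int]]] = {e: {} for e in experts}
    for name in profile.score_means:
        mu = np.array([profile.score_means[name][c] for c in cids])
        sd = np.array([profile.score_sds[name][c] for c in cids])
        draws = rng.normal(mu, sd, size=(profile.n_experts, len(cids)))
        for j, c in enumerate(fw.criteria):
            col = _discretize(draws[:, j], c.scale.lower, c.scale.upper)
            for i, e in enumerate(experts):
                scores[e].setdefault(name, {})[c.id] = int(col[i])

    return RatingSheet(ratings), ExpertScoreSheet(scores)


def default_profile(seed: int = 0,
                    n_experts: int = DEFAULT_N_EXPERTS) -> PanelProfile:
    """A realistic appraisal panel for the two acid blockers.

    Score means/SDs are the published panel summary; latent weight-rating
    means encode the qualitative weight structure the panel reported (unmet
    needs weighted highest in its domain, effectiveness and safety equal,
    drug costs > other medical costs > non-medical costs).
    """
    fw = core_framework()
    summaries = reference_panel_scores()
    rating_means = {
        "disease_severity": 3.0,
        "population_size": 3.0,
        "unmet_needs": 5.0,
        "comparative_effectiveness": 4.0,
        "comparative_safety": 4.0,
        "patient_perceived_health": 3.0,
        "preventive_benefit": 3.0,
        "therapeutic_benefit": 4.0,
        "intervention_costs": 4.0,
        "other_medical_costs": 3.0,
        "non_medical_costs": 2.0,
        "quality_of_evidence": 3.0,
        "guidelines": 4.0,
    }
    return PanelProfile(
        framework=fw,
        rating_means=rating_means,
        score_means={name: dict(s.means) for name, s in summaries.items()},
        score_sds={name: dict(s.sds) for name, s in summaries.items()},
        n_experts=n_experts,
        seed=seed,
    )


def reference_panel_scores() -> dict[str, ScoreSummary]:
    """The published 14-expert panel score summary (mean +/- SD per criterion)
    for vonoprazan ('VPZ') and tegoprazan ('TPZ').

    Criteria with no retrieved evidence (non-medical costs for both drugs,
    other medical costs for TPZ) carry score 0 and a 'no-evidence' annotation.
    """
    ref = resources.files("evidem").joinpath("data/panel_scores_vpz_tpz.csv")
    with resources.as_file(ref) as path:
        return read_score_summaries(path, n_experts=DEFAULT_N_EXPERTS)


def affordability_share(cost: float | str | Decimal,
                        income: float | str | Decimal) -> float:
    """Cost as a percentage of per-capita disposable income, half-up rounded
    to 1 decimal. Amounts are handled as exact decimals so currency inputs
    with two fractional digits never drift."""
    cost_d = Decimal(str(cost))
    income_d = Decimal(str(income))
    if income_d <= 0:
        raise ValidationError(f"income must be positive, got {income}")
    if cost_d < 0:
        raise ValidationError(f"cost must be >= 0, got {cost}")
    share = Decimal(100) * cost_d / income_d
    return float(share.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
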