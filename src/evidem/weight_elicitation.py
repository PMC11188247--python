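"""Criterion weight elicitation.

Two elicitation back-ends produce the same :class:`~evidem.core_model.WeightVector`:

* **direct rating** — each panel expert rates every criterion's impact on the
  value of a medicine on a 5-point scale (5 = decisive, 1 = inessential);
  the raw weight of a criterion is the arithmetic mean of the expert ratings.
* **analytic hierarchy process (AHP)** — weights are the principal right
  eigenvector of a positive reciprocal pairwise-comparison matrix, with
  Saaty's consistency ratio CR = CI / RI as the judgment-quality diagnostic,
  CI = (lambda_max - n) / (n - 1).

Several experts' AHP matrices are combined by the element-wise geometric
mean (aggregation of individual judgments) before eigenvector extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import FrameworkDefinition, WeightVector
from .errors import NumericalError, StructuralError, ValidationError

__all__ = [
    "RatingSheet",
    "PairwiseMatrix",
    "ConsistencyReport",
    "direct_weights",
    "ahp_weights",
    "check_consistency",
    "aggregate_pairwise",
    "SAATY_RANDOM_INDEX",
]

#: Saaty's random consistency index, indexed by matrix order (1-based, orders 1-15).
SAATY_RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

RATING_MIN, RATING_MAX = 1, 5


@dataclass(frozen=True)
class RatingSheet:
    """Per-expert integer impact ratings (1..5) for every criterion."""

    ratings: Mapping[str, Mapping[str, int]]  # expert_id -> criterion_id -> rating

    def __post_init__(self) -> None:
        if not self.ratings:
            raise StructuralError("rating sheet has no experts")
        clean: dict[str, dict[str, int]] = {}
        reference = None
        for expert, row in self.ratings.items():
            for cid, r in row.items():
                if not (isinstance(r, (int, np.integer)) and not isinstance(r, bool)):
                    raise ValidationError(
                        f"expert {expert!r}, criterion {cid!r}: rating {r!r} is not an integer"
                    )
                if not (RATING_MIN <= r <= RATING_MAX):
                    raise ValidationError(
                        f"expert {expert!r}, criterion {cid!r}: rating {r} outside "
                        f"[{RATING_MIN}, {RATING_MAX}]"
                    )
            keys = frozenset(row)
            if reference is None:
                reference = keys
            elif keys != reference:
                raise StructuralError(
                    f"expert {expert!r} rated a different criterion set than the first expert"
                )
            clean[expert] = {cid: int(r) for cid, r in row.items()}
        object.__setattr__(self, "ratings", clean)

    @property
    def experts(self) -> tuple[str, ...]:
        return tuple(self.ratings)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        first = next(iter(self.ratings.values()))
        return tuple(first)

    # -- CSV interface: expert_id, criterion_id, rating -----------------

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"expert_id": e, "criterion_id": c, "rating": r}
            for e, row in self.ratings.items()
            for c, r in row.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingSheet":
        df = pd.read_csv(path, comment="#")
        required = {"expert_id", "criterion_id", "rating"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"rating sheet CSV must have columns {sorted(required)}"
            )
        ratings: dict[str, dict[str, int]] = {}
        for rec in df.itertuples(index=False):
            val = rec.rating
            if float(val) != int(val):
                raise ValidationError(
                    f"expert {rec.expert_id!r}, criterion {rec.criterion_id!r}: "
                    f"rating {val} is not an integer"
                )
            ratings.setdefault(str(rec.expert_id), {})[str(rec.criterion_id)] = int(val)
        return cls(ratings)


def direct_weights(sheet: RatingSheet, framework: FrameworkDefinition) -> WeightVector:
    """Mean-of-ratings weights: raw W_x = mean over experts of the 1..5 rating."""
    have, want = set(sheet.criterion_ids), set(framework.criterion_ids)
    if have != want:
        raise StructuralError(
            f"rating sheet does not cover the framework: missing {sorted(want - have)}, "
            f"extra {sorted(have - want)}"
        )
    raw = {
        cid: float(np.mean([sheet.ratings[e][cid] for e in sheet.experts]))
        for cid in framework.criterion_ids
    }
    return WeightVector(raw)


@dataclass(frozen=True)
class PairwiseMatrix:
    """Positive reciprocal pairwise-comparison matrix over an ordered
    criterion list; a_ij estimates w_i / w_j."""

    criterion_ids: tuple[str, ...]
    values: np.ndarray
    reciprocity_tol: float = 1e-9

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        n = len(self.criterion_ids)
        if a.shape != (n, n):
            raise ValidationError(
                f"matrix shape {a.shape} does not match {n} criteria"
            )
        if n < 2:
            raise ValidationError("pairwise matrix needs at least 2 criteria")
        if len(set(self.criterion_ids)) != n:
            raise ValidationError("duplicate criterion ids in pairwise matrix")
        if not np.all(a > 0):
            raise ValidationError("pairwise matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=self.reciprocity_tol):
            raise ValidationError("pairwise matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=self.reciprocity_tol):
            raise ValidationError("pairwise matrix is not reciprocal (a_ij * a_ji != 1)")
        object.__setattr__(self, "criterion_ids", tuple(self.criterion_ids))
        object.__setattr__(self, "values", a)

    @property
    def order(self) -> int:
        return len(self.criterion_ids)

    # -- CSV interface: square table with criterion ids as header row/column

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.criterion_ids,
                          columns=self.criterion_ids)
        df.to_csv(path, index_label="criterion_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        ids = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != ids:
            raise ValidationError("pairwise matrix CSV row/column ids differ")
        return cls(ids, df.to_numpy(dtype=float))

    @classmethod
    def from_weights(cls, weights: Mapping[str, float]) -> "PairwiseMatrix":
        """Perfectly consistent matrix a_ij = w_i / w_j from a positive vector."""
        ids = tuple(weights)
        w = np.array([weights[c] for c in ids], dtype=float)
        if not np.all(w > 0):
            raise ValidationError("weights must be positive")
        return cls(ids, np.outer(w, 1.0 / w))


@dataclass(frozen=True)
class ConsistencyReport:
    """AHP consistency diagnostics for one pairwise matrix."""

    order: int
    lambda_max: float
    ci: float
    ri: float | None
    cr: float | None
    threshold: float = 0.1

    @property
    def consistent(self) -> bool:
        """Pass flag: CR <= threshold (CI <= threshold when CR is undefined)."""
        stat = self.cr if self.cr is not None else self.ci
        return stat <= self.threshold


def _principal_eigenvector(a: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Power iteration for a positive matrix: Perron vector (sum 1) and lambda_max."""
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for iteration in range(1, max_iter + 1):
        nxt = a @ w
        nxt /= nxt.sum()
        change = np.max(np.abs(nxt - w) / np.maximum(np.abs(w), 1e-300))
        w = nxt
        if change < tol:
            aw = a @ w
            lambda_max = float(np.mean(aw / w))
            return w, lambda_max
    raise NumericalError(
        f"power iteration did not converge in {max_iter} iterations (tol {tol})"
    )


def _consistency(lambda_max: float, n: int, threshold: float) -> ConsistencyReport:
    ci = (lambda_max - n) / (n - 1) if n >= 2 else 0.0
    # lambda_max >= n for positive reciprocal matrices; tiny negative CI is
    # numerical noise from the power iteration.
    if abs(ci) < 1e-12:
        ci = 0.0
    if n >= 3:
        if n not in SAATY_RANDOM_INDEX:
            raise ValidationError(
                f"no random consistency index tabulated for matrix order {n} (max 15)"
            )
        ri = SAATY_RANDOM_INDEX[n]
        cr = ci / ri
        if abs(cr) < 1e-12:
            cr = 0.0
    else:
        ri, cr = None, None  # CR undefined below order 3; CI reported alone
    return ConsistencyReport(order=n, lambda_max=lambda_max, ci=ci, ri=ri,
                             cr=cr, threshold=threshold)


def ahp_weights(matrix: PairwiseMatrix, tol: float = 1e-10,
                max_iter: int = 10_000,
                cr_threshold: float = 0.1) -> tuple[WeightVector, ConsistencyReport]:
    """Principal-eigenvector AHP weights with a consistency report.

    The weight vector is normalized to sum 1; the report carries lambda_max,
    CI and (for order >= 3) CR against Saaty's random index.
    """
    w, lambda_max = _principal_eigenvector(matrix.values, tol=tol, max_iter=max_iter)
    report = _consistency(lambda_max, matrix.order, cr_threshold)
    raw = {cid: float(wi) for cid, wi in zip(matrix.criterion_ids, w)}
    return WeightVector(raw), report


def check_consistency(matrix: PairwiseMatrix,
                      threshold: float = 0.1) -> ConsistencyReport:
    """Consistency diagnostics only (CR for order >= 3, CI alone for order 2)."""
    _, lambda_max = _principal_eigenvector(matrix.values)
    return _consistency(lambda_max, matrix.order, threshold)


def aggregate_pairwise(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Combine several experts' matrices by the element-wise geometric mean
    (aggregation of individual judgments); the result is again reciprocal."""
    if not matrices:
        raise StructuralError("no pairwise matrices to aggregate")
    ids = matrices[0].criterion_ids
    for m in matrices[1:]:
        if m.criterion_ids != ids:
            raise StructuralError("pairwise matrices have different criterion orderings")
    stack = np.stack([m.values for m in matrices])
    agg = np.exp(np.mean(np.log(stack), axis=0))
    # symmetrize accumulated float error: for reciprocal inputs
    # sqrt(a_ij / a_ji) == a_ij and the result is reciprocal to machine precision
    agg = np.sqrt(agg / agg.T)
    np.fill_diagonal(agg, 1.0)
    return PairwiseMatrix(ids, agg)
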