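"""Monte Carlo propagation, tornado weight sensitivity, inverse calibration."""

import numpy as np
import pytest

from evidem import (
    FrameworkDefinition,
    ScoreSummary,
    ValidationError,
    WeightVector,
    compute_value,
)
from evidem.analysis import (
    CalibrationProblem,
    OrderingConstraint,
    calibrate_weights,
    monte_carlo_values,
    tornado_weights,
)
from evidem.core_model import Criterion, Domain, ScoringScale


@pytest.fixture(scope="module")
def toy_framework():
    return FrameworkDefinition(
        domains=(Domain("d1", "D1"), Domain("d2", "D2")),
        criteria=(
            Criterion("c1", "C1", "d1", ScoringScale("absolute")),
            Criterion("c2", "C2", "d1", ScoringScale("relative")),
            Criterion("c3", "C3", "d2", ScoringScale("absolute")),
        ),
    )


def _toy_summary(name, means, sds, fw):
    cids = fw.criterion_ids
    return ScoreSummary(name, dict(zip(cids, means)), dict(zip(cids, sds)))


class TestMonteCarlo:
    def test_degenerate_sds_give_certain_ranking(self, toy_framework):
        a = _toy_summary("A", [4, 2, 3], [0, 0, 0], toy_framework)
        b = _toy_summary("B", [2, 1, 3], [0, 0, 0], toy_framework)
        wv = WeightVector.uniform(toy_framework)
        result = monte_carlo_values(a, b, wv, toy_framework, n_draws=500, seed=0)
        assert result.p_a_gt_b == 1.0
        assert result.means["A"] == pytest.approx(9 / 15, abs=1e-12)

    def test_identical_distributions_give_half(self, toy_framework):
        means, sds = [3, 1, 2], [0.8, 0.8, 0.8]
        a = _toy_summary("A", means, sds, toy_framework)
        b = _toy_summary("B", means, sds, toy_framework)
        wv = WeightVector.uniform(toy_framework)
        result = monte_carlo_values(a, b, wv, toy_framework, n_draws=10_000, seed=42)
        assert result.p_a_gt_b == pytest.approx(0.5, abs=0.02)  # 4x MC standard error

    def test_same_seed_bitwise_identical(self, framework, summaries, uniform_weights):
        kwargs = dict(n_draws=200, seed=123)
        r1 = monte_carlo_values(summaries["VPZ"], summaries["TPZ"], uniform_weights,
                                framework, **kwargs)
        r2 = monte_carlo_values(summaries["VPZ"], summaries["TPZ"], uniform_weights,
                                framework, **kwargs)
        assert r1 == r2

    def test_percentiles_ordered_and_probability_in_unit_interval(
            self, framework, summaries, uniform_weights):
        r = monte_carlo_values(summaries["VPZ"], summaries["TPZ"], uniform_weights,
                               framework, n_draws=500, seed=5)
        assert 0.0 <= r.p_a_gt_b <= 1.0
        for lo, hi in r.percentiles.values():
            assert lo <= hi

    def test_sampled_scores_respect_scale_bounds(self, toy_framework):
        # means at the scale edges with large sds: totals still bounded by the
        # truncation, so V stays within the all-max envelope
        a = _toy_summary("A", [5, 5, 5], [3, 3, 3], toy_framework)
        b = _toy_summary("B", [0, -5, 0], [3, 3, 3], toy_framework)
        wv = WeightVector.uniform(toy_framework)
        r = monte_carlo_values(a, b, wv, toy_framework, n_draws=2000, seed=9)
        assert r.percentiles["A"][1] <= 1.0 + 1e-12
        assert r.percentiles["B"][0] >= -10 / 15 - 1e-12  # min attainable mean mix

    def test_p_monotone_in_value_gap(self, toy_framework):
        """Shifting A's means upward (same sds) never decreases p_a_gt_b."""
        wv = WeightVector.uniform(toy_framework)
        b = _toy_summary("B", [3, 0, 3], [0.7, 0.7, 0.7], toy_framework)
        previous = -1.0
        for shift in (0.0, 0.5, 1.0, 1.5):
            a = _toy_summary("A", [3 + shift, 0 + shift, 3 + shift],
                             [0.7, 0.7, 0.7], toy_framework)
            p = monte_carlo_values(a, b, wv, toy_framework,
                                   n_draws=10_000, seed=77).p_a_gt_b
            assert p >= previous - 0.02
            previous = p

    @pytest.mark.parametrize("bad_kwargs", [{"n_draws": 0}, {"seed": -1},
                                            {"n_draws": 2.5}])
    def test_invalid_mc_parameters_rejected(self, toy_framework, bad_kwargs):
        a = _toy_summary("A", [3, 0, 3], [0, 0, 0], toy_framework)
        b = _toy_summary("B", [2, 0, 3], [0, 0, 0], toy_framework)
        kwargs = {"n_draws": 10, "seed": 0, **bad_kwargs}
        with pytest.raises(ValidationError):
            monte_carlo_values(a, b, WeightVector.uniform(toy_framework),
                               toy_framework, **kwargs)


class TestTornado:
    def test_identical_scores_give_zero_swings(self, toy_framework):
        s = _toy_summary("A", [4, 2, 3], [0, 0, 0], toy_framework)
        t = _toy_summary("B", [4, 2, 3], [0, 0, 0], toy_framework)
        r = tornado_weights(WeightVector.uniform(toy_framework), s, t,
                            toy_framework, delta=1.0)
        assert all(e.delta_diff == pytest.approx(0.0, abs=1e-12) for e in r.entries)

    def test_zero_delta_changes_nothing(self, framework, summaries, uniform_weights):
        r = tornado_weights(uniform_weights, summaries["VPZ"], summaries["TPZ"],
                            framework, delta=0.0)
        for e in r.entries:
            assert e.v_a_plus == pytest.approx(r.base_v_a, abs=1e-12)
            assert e.v_b_minus == pytest.approx(r.base_v_b, abs=1e-12)

    def test_equal_scored_criterion_preserves_gap_sign(self, framework, summaries):
        """Perturbing a criterion where both drugs score identically rescales
        the gap but never flips its sign."""
        wv = WeightVector({cid: 3.0 for cid in framework.criterion_ids})
        r = tornado_weights(wv, summaries["VPZ"], summaries["TPZ"], framework,
                            delta=1.0)
        base_sign = np.sign(r.base_v_a - r.base_v_b)
        equal_criteria = {
            cid for cid in framework.criterion_ids
            if summaries["VPZ"].means[cid] == summaries["TPZ"].means[cid]
        }
        for e in r.entries:
            if e.criterion_id in equal_criteria:
                assert np.sign(e.v_a_plus - e.v_b_plus) == base_sign
                assert np.sign(e.v_a_minus - e.v_b_minus) == base_sign

    def test_top_criterion_is_economic_with_uniform_weights(
            self, framework, summaries, uniform_weights):
        # brute-force oracle: recompute all 13 perturbations directly
        r = tornado_weights(uniform_weights, summaries["VPZ"], summaries["TPZ"],
                            framework, delta=1.0)
        swings = {}
        for cid in framework.criterion_ids:
            per_sign = {}
            for sign in (+1, -1):
                raw = dict(uniform_weights.raw)
                raw[cid] = min(max(raw[cid] + sign, 1.0), 5.0)
                wv = WeightVector(raw)
                per_sign[sign] = (
                    compute_value(wv, summaries["VPZ"], framework).total
                    - compute_value(wv, summaries["TPZ"], framework).total
                )
            swings[cid] = per_sign[+1] - per_sign[-1]
        expected_top = max(swings, key=lambda c: abs(swings[c]))
        assert r.entries[0].criterion_id == expected_top
        assert framework.criterion(expected_top).domain_id == "economic"


class TestCalibration:
    def test_headline_pair_jointly_feasible(self, framework, summaries,
                                            ordering_constraints):
        problem = CalibrationProblem(
            framework=framework,
            summaries=summaries,
            targets={"VPZ": 0.59, "TPZ": 0.54},
            constraints=ordering_constraints,
        )
        result = calibrate_weights(problem)
        assert result.feasible
        assert result.achieved_rounded == {"VPZ": 0.59, "TPZ": 0.54}
        raw = result.weights.raw
        # every ordering constraint holds exactly, bounds respected
        for con in ordering_constraints:
            assert con.satisfied(raw), str(con)
        assert raw["comparative_effectiveness"] == raw["comparative_safety"]
        assert all(1.0 <= w <= 5.0 for w in raw.values())

    def test_uniform_targets_trivially_feasible(self, framework, summaries,
                                                uniform_weights):
        targets = {
            name: round(compute_value(uniform_weights, s, framework).total, 2)
            for name, s in summaries.items()
        }
        problem = CalibrationProblem(framework=framework, summaries=summaries,
                                     targets=targets)
        result = calibrate_weights(problem)
        assert result.feasible

    def test_unattainable_target_reports_infeasibility(self, framework, summaries):
        problem = CalibrationProblem(framework=framework, summaries=summaries,
                                     targets={"VPZ": 2.0, "TPZ": 0.5})
        result = calibrate_weights(problem)
        assert not result.feasible
        assert "range" in result.message

    def test_contradictory_constraints_rejected(self, framework, summaries):
        with pytest.raises(ValidationError, match="contradictory"):
            CalibrationProblem(
                framework=framework, summaries=summaries,
                targets={"VPZ": 0.5, "TPZ": 0.5},
                constraints=(
                    OrderingConstraint("gt", "unmet_needs", "disease_severity"),
                    OrderingConstraint("gt", "disease_severity", "unmet_needs"),
                ),
            )

    def test_constraint_referencing_unknown_criterion_rejected(self, framework,
                                                               summaries):
        with pytest.raises(ValidationError, match="unknown"):
            CalibrationProblem(
                framework=framework, summaries=summaries,
                targets={"VPZ": 0.5, "TPZ": 0.5},
                constraints=(OrderingConstraint("gt", "nope", "unmet_needs"),),
            )

    def test_calibration_is_deterministic(self, framework, summaries,
                                          ordering_constraints):
        problem = CalibrationProblem(
            framework=framework, summaries=summaries,
            targets={"VPZ": 0.59, "TPZ": 0.54}, constraints=ordering_constraints,
        )
        r1 = calibrate_weights(problem)
        r2 = calibrate_weights(problem)
        assert r1.weights.raw == r2.weights.raw
        assert r1.achieved == r2.achieved
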