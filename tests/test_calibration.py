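"""Calibration: loss at truth, recovery, stability, identifiability."""
import numpy as np
import pytest

import frailtysim as fs
from frailtysim.calibration import (
    BaselineSetup,
    CalibrationProblem,
    FreeParameter,
    Target,
    calibrate,
)
from frailtysim.params import TRANSITIONS
from frailtysim.structure import AGE_BANDS, FRAILTY_STATES, ValidationError

YEARS = tuple(range(2025, 2041))


def transition_recovery_problem(truth, rich_targets=True):
    """Free the 12 transition rates against engine-generated observables."""
    inc = fs.annual_incidence(truth.trajectory, append_total=False)
    targets = [Target(f"incidence:{b}", YEARS, inc[b].to_numpy())
               for b in AGE_BANDS]
    if rich_targets:
        for b_i, b in enumerate(AGE_BANDS):
            for s_i, st in enumerate(FRAILTY_STATES[1:], start=1):
                vals = np.array([sv.counts[b_i, s_i]
                                 for sv in truth.trajectory.stocks])
                targets.append(Target(f"stock:{b}:{st}", YEARS, vals))
    else:
        targets += [
            Target("frail_total", YEARS,
                   truth.trajectory.frail_series().to_numpy()),
            Target("moderate_severe_total", YEARS,
                   truth.trajectory.moderate_severe_series().to_numpy()),
        ]
    free = tuple(FreeParameter(f"transition:{b}:{tr}", 0.001, 0.5)
                 for b in AGE_BANDS for tr in TRANSITIONS)
    base = BaselineSetup(truth.params, truth.initial, truth.entries)
    return CalibrationProblem(free, base, tuple(targets))


def perturbed_start(truth, factor=1.5):
    return {f"transition:{b}:{tr}": float(
        np.clip(truth.params.transition[bi, ti] * factor, 0.001, 0.5))
        for bi, b in enumerate(AGE_BANDS)
        for ti, tr in enumerate(TRANSITIONS)}


def recovery_errors(truth, result):
    return [abs(result.values[f"transition:{b}:{tr}"]
                - truth.params.transition[bi, ti])
            / truth.params.transition[bi, ti]
            for bi, b in enumerate(AGE_BANDS)
            for ti, tr in enumerate(TRANSITIONS)]


class TestCalibrate:
    def test_zero_free_parameters_returns_direct_loss(self, truth):
        problem = CalibrationProblem(
            (), BaselineSetup(truth.params, truth.initial, truth.entries),
            (Target("frail_total", YEARS,
                    truth.trajectory.frail_series().to_numpy()),))
        res = calibrate(problem, 2025, 2040)
        assert res.converged and res.values == {}
        assert res.loss == pytest.approx(0.0, abs=1e-15)

    def test_loss_at_truth_is_zero(self, truth):
        """Evaluating the loss at the generating parameters on noiseless
        targets gives zero within 1e-12."""
        problem = transition_recovery_problem(truth)
        res = calibrate(problem, 2025, 2040,
                        x0={f.name: truth.params.transition[
                            AGE_BANDS.index(f.name.split(":")[1]),
                            TRANSITIONS.index(f.name.split(":")[2])]
                            for f in problem.free})
        assert res.loss <= 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_transition_rates_recovered_within_one_percent(self, seed):
        truth = fs.make_truth(fs.GeneratorConfig(seed=seed))
        problem = transition_recovery_problem(truth)
        res = calibrate(problem, 2025, 2040, x0=perturbed_start(truth, 1.4))
        assert max(recovery_errors(truth, res)) < 0.01
        assert res.converged

    def test_multistart_stability(self, truth):
        """Starts at truth x 1.5 and truth x 0.7 reach the same fitted
        values within 1e-4."""
        problem = transition_recovery_problem(truth)
        res_hi = calibrate(problem, 2025, 2040, x0=perturbed_start(truth, 1.5))
        res_lo = calibrate(problem, 2025, 2040, x0=perturbed_start(truth, 0.7))
        for name in res_hi.values:
            assert res_hi.values[name] == pytest.approx(
                res_lo.values[name], abs=1e-4)

    def test_fitted_values_respect_bounds(self, truth):
        problem = transition_recovery_problem(truth)
        res = calibrate(problem, 2025, 2040, x0=perturbed_start(truth))
        for f in problem.free:
            assert f.lo - 1e-12 <= res.values[f.name] <= f.hi + 1e-12

    def test_flat_direction_reported_not_masked(self, truth):
        """A free parameter with no influence on the targets must be
        flagged as unidentifiable."""
        inc = fs.annual_incidence(truth.trajectory, append_total=False)
        targets = (Target("incidence:50-64", YEARS,
                          inc["50-64"].to_numpy()),)
        free = (
            FreeParameter("transition:50-64:fit_mild", 0.001, 0.5),
            # severe-state mortality in another band cannot move incidence
            FreeParameter("mortality:85+:severe", 0.001, 0.5),
        )
        problem = CalibrationProblem(
            free, BaselineSetup(truth.params, truth.initial, truth.entries),
            targets)
        res = calibrate(problem, 2025, 2040)
        assert res.identifiable is False
        assert res.jacobian_rank == 1

    def test_deterministic_given_start(self, truth):
        problem = transition_recovery_problem(truth)
        a = calibrate(problem, 2025, 2040, x0=perturbed_start(truth))
        b = calibrate(problem, 2025, 2040, x0=perturbed_start(truth))
        assert a.values == b.values and a.loss == b.loss

    def test_more_free_parameters_than_points_rejected(self, truth):
        free = tuple(FreeParameter(f"transition:{b}:{tr}", 0.0, 0.5)
                     for b in AGE_BANDS for tr in TRANSITIONS)
        targets = (Target("frail_total", (2025, 2040),
                          np.array([1e6, 1e6])),)
        with pytest.raises(ValidationError):
            CalibrationProblem(
                free, BaselineSetup(truth.params, truth.initial, truth.entries),
                targets)


class TestMakeTruthHarness:
    def test_truth_observables_give_zero_loss_as_targets(self, truth):
        problem = transition_recovery_problem(truth, rich_targets=False)
        res = calibrate(problem, 2025, 2040, x0={
            f.name: truth.params.transition[
                AGE_BANDS.index(f.name.split(":")[1]),
                TRANSITIONS.index(f.name.split(":")[2])]
            for f in problem.free})
        assert res.loss <= 1e-12

    def test_two_seeds_give_different_truths(self):
        t1 = fs.make_truth(fs.GeneratorConfig(seed=1), 2025, 2030)
        t2 = fs.make_truth(fs.GeneratorConfig(seed=2), 2025, 2030)
        assert not np.array_equal(t1.params.transition, t2.params.transition)

    def test_truth_trajectory_satisfies_engine_invariants(self, truth):
        traj = truth.trajectory
        for sv in traj.stocks:
            assert np.all(sv.counts >= 0)
        for sv, fl in zip(traj.stocks[:-1], traj.flows):
            nxt = traj.stock(sv.year + 1)
            assert nxt.total() == pytest.approx(
                sv.total() - fl.total_deaths() + fl.total_entries(), rel=1e-9)
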