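"""Bounded least-squares recovery of unprinted model parameters.

The engine's source rates (transition, mortality, entry mix, service
rates) are typically estimated from individual-level records that are not
released alongside aggregate projections. This module recovers them by
fitting the engine's observable outputs — incidence per band, frail and
population totals, contact and cost series — to target trajectories,
either packaged reference tables or synthetic truths.

Free parameters are addressed by name, e.g. ``transition:65-74:fit_mild``,
``mortality:85+:severe``, ``initial:50-64:fit``, ``entries:2030``,
``entry_mix:mild``. The loss is a weighted sum of squared *relative*
residuals, so person-count targets (millions) and cost targets (GBP
millions) mix without manual rescaling. Minimisation uses a bounded
trust-region reflective solver; given the same starting point the result
is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import Trajectory, annual_incidence, capped_outflow_rates, run
from .params import EntrySchedule, ParameterSet, TRANSITION_INDEX, TRANSITIONS
from .services import (
    CATEGORY_INDEX,
    ServiceRateSet,
    UnitCostSet,
    project_contacts,
    project_costs,
)
from .structure import (
    AGE_BANDS,
    BAND_INDEX,
    FRAILTY_STATES,
    STATE_INDEX,
    StockVector,
    ValidationError,
)

__all__ = [
    "BaselineSetup",
    "FreeParameter",
    "Target",
    "CalibrationProblem",
    "CalibrationResult",
    "calibrate",
]


@dataclass(frozen=True)
class BaselineSetup:
    """Fixed model world a calibration perturbs: parameters, initial
    stocks, entry schedule and (optionally) the service overlay."""

    params: ParameterSet
    initial: StockVector
    entries: EntrySchedule
    service_rates: ServiceRateSet | None = None
    unit_costs: UnitCostSet | None = None


@dataclass(frozen=True)
class FreeParameter:
    """One named free entry with box bounds ``[lo, hi]``."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo <= self.hi):
            raise ValidationError(f"invalid bounds for {self.name}: [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Target:
    """One observable series with target values and a weight.

    ``observable`` is one of the registered names below; ``years`` and
    ``values`` are aligned. Weights multiply the squared relative
    residuals.
    """

    observable: str
    years: tuple[int, ...]
    values: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.years),):
            raise ValidationError(
                f"target {self.observable}: {len(self.years)} years but "
                f"{vals.shape} values")
        if self.weight < 0:
            raise ValidationError("target weight must be >= 0")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))


@dataclass(frozen=True)
class CalibrationProblem:
    free: tuple[FreeParameter, ...]
    base: BaselineSetup
    targets: tuple[Target, ...]

    def __post_init__(self) -> None:
        n_points = sum(len(t.years) for t in self.targets if t.weight > 0)
        if self.free and n_points < len(self.free):
            raise ValidationError(
                f"{len(self.free)} free parameters but only {n_points} "
                "weighted target points")
        names = [f.name for f in self.free]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate free-parameter names")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a calibration run.

    ``identifiable`` is False when the Jacobian at the solution is rank
    deficient (flat directions): the fit is then one of a family of
    equally good solutions and individual values should not be
    over-interpreted.
    """

    values: dict[str, float]
    loss: float
    residuals: pd.DataFrame
    converged: bool
    message: str
    x0: np.ndarray
    nfev: int
    jacobian_rank: int | None = None
    identifiable: bool | None = None

    def fitted_setup(self, problem: CalibrationProblem) -> BaselineSetup:
        return _apply_values(problem.base, self.values)


# --------------------------------------------------------------------------
# Parameter addressing
# --------------------------------------------------------------------------

def _apply_values(base: BaselineSetup, values: dict[str, float]) -> BaselineSetup:
    """A copy of ``base`` with the named entries replaced.

    If any ``entry_mix:*`` entry is set, the mix is renormalised to the
    simplex afterwards (free mix entries are raw weights).
    """
    transition = base.params.transition.copy()
    mortality = base.params.mortality.copy()
    ageing = base.params.ageing.copy()
    entry_mix = base.params.entry_mix.copy()
    initial = base.initial.counts.copy()
    entries = base.entries.values.copy()
    svc = base.service_rates.rates.copy() if base.service_rates is not None else None
    mix_touched = False

    for name, val in values.items():
        parts = name.split(":")
        kind = parts[0]
        if kind == "transition":
            _, band, tr = parts
            transition[BAND_INDEX[band], TRANSITION_INDEX[tr]] = val
        elif kind == "mortality":
            _, band, state = parts
            mortality[BAND_INDEX[band], STATE_INDEX[state]] = val
        elif kind == "ageing":
            ageing[BAND_INDEX[parts[1]]] = val
        elif kind == "entry_mix":
            entry_mix[STATE_INDEX[parts[1]]] = val
            mix_touched = True
        elif kind == "initial":
            _, band, state = parts
            initial[BAND_INDEX[band], STATE_INDEX[state]] = val
        elif kind == "entries":
            year = int(parts[1])
            entries[year - base.entries.start_year] = val
        elif kind == "service_rate":
            if svc is None:
                raise ValidationError("no service rates in baseline setup")
            _, band, state, cat = parts
            svc[BAND_INDEX[band], STATE_INDEX[state], CATEGORY_INDEX[cat]] = val
        else:
            raise ValidationError(f"unknown parameter name {name!r}")

    if mix_touched:
        s = entry_mix.sum()
        if s <= 0:
            raise ValidationError("entry_mix weights sum to zero")
        entry_mix = entry_mix / s

    params = ParameterSet(transition, mortality, ageing, entry_mix)
    return BaselineSetup(
        params=params,
        initial=StockVector(initial, base.initial.year),
        entries=EntrySchedule(base.entries.start_year, entries),
        service_rates=ServiceRateSet(svc) if svc is not None else None,
        unit_costs=base.unit_costs,
    )


# --------------------------------------------------------------------------
# Observables
# --------------------------------------------------------------------------

def _observable_series(setup: BaselineSetup, traj: Trajectory,
                       name: str) -> pd.Series:
    """Evaluate one named observable as a year-indexed series."""
    if name.startswith("incidence:"):
        band = name.split(":", 1)[1]
        inc = annual_incidence(traj, append_total=False)
        col = "Overall" if band == "overall" else band
        return inc[col]
    if name == "frail_total":
        return traj.frail_series()
    if name == "fit_total":
        return pd.Series({sv.year: float(sv.counts[:, 0].sum())
                          for sv in traj.stocks}, name="fit")
    if name == "population_total":
        return traj.total_series()
    if name == "moderate_severe_total":
        return traj.moderate_severe_series()
    if name.startswith("stock:"):
        _, band, state = name.split(":")
        bi, si = BAND_INDEX[band], STATE_INDEX[state]
        return pd.Series({sv.year: float(sv.counts[bi, si])
                          for sv in traj.stocks}, name=name)
    if name.startswith(("contacts:", "costs:")):
        if setup.service_rates is None:
            raise ValidationError(f"observable {name!r} needs service rates")
        contacts = project_contacts(traj, setup.service_rates)
        which, sector, group = name.split(":")
        if which == "contacts":
            return contacts.table[(sector, group)]
        if setup.unit_costs is None:
            raise ValidationError(f"observable {name!r} needs unit costs")
        costs = project_costs(contacts, setup.unit_costs)
        return costs.table[(sector, group)]
    raise ValidationError(f"unknown observable {name!r}")


def evaluate_residuals(problem: CalibrationProblem, values: dict[str, float],
                       start_year: int, end_year: int) -> pd.DataFrame:
    """Weighted relative residuals of every target point at ``values``."""
    setup = _apply_values(problem.base, values)
    traj = run(setup.initial, setup.params, setup.entries, start_year, end_year)
    rows = []
    for t in problem.targets:
        series = _observable_series(setup, traj, t.observable)
        for year, obs in zip(t.years, t.values):
            pred = float(series.loc[year])
            scale = abs(obs) if obs != 0 else 1.0
            rows.append({
                "observable": t.observable, "year": year, "target": obs,
                "predicted": pred, "rel_residual": (pred - obs) / scale,
                "weight": t.weight,
            })
    return pd.DataFrame(rows)


def _loss_from_residuals(df: pd.DataFrame) -> float:
    return float((df["weight"] * df["rel_residual"] ** 2).sum())


def calibrate(problem: CalibrationProblem, start_year: int, end_year: int,
              x0: np.ndarray | dict[str, float] | None = None,
              max_nfev: int | None = None,
              xtol: float = 1e-10, ftol: float = 1e-10, gtol: float = 1e-10,
              ) -> CalibrationResult:
    """Fit the free parameters by bounded least squares.

    ``x0`` defaults to the baseline setup's current values (clipped to
    bounds); pass a dict or vector to start elsewhere. Deterministic given
    the starting point. The result always reports the achieved loss and
    residuals; ``converged`` is False when the solver stopped on its
    evaluation budget rather than a tolerance.
    """
    free = problem.free
    if not free:
        resid = evaluate_residuals(problem, {}, start_year, end_year)
        return CalibrationResult(
            values={}, loss=_loss_from_residuals(resid), residuals=resid,
            converged=True, message="no free parameters", x0=np.empty(0),
            nfev=1, jacobian_rank=0, identifiable=True)

    lo = np.array([f.lo for f in free])
    hi = np.array([f.hi for f in free])

    base_values = _current_values(problem.base, [f.name for f in free])
    if x0 is None:
        x_start = np.clip(base_values, lo, hi)
    elif isinstance(x0, dict):
        x_start = np.clip(np.array([x0[f.name] for f in free]), lo, hi)
    else:
        x_start = np.clip(np.asarray(x0, dtype=float), lo, hi)

    names = [f.name for f in free]
    sqw_cache: dict[int, np.ndarray] = {}

    def residual_vec(x: np.ndarray) -> np.ndarray:
        df = evaluate_residuals(problem, dict(zip(names, x)),
                                start_year, end_year)
        return np.sqrt(df["weight"].to_numpy()) * df["rel_residual"].to_numpy()

    # strictly feasible bounds for trf when lo == hi
    hi_eff = np.where(hi > lo, hi, lo + 1e-15)
    sol = least_squares(residual_vec, x_start, bounds=(lo, hi_eff),
                        method="trf", x_scale="jac",
                        xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=max_nfev)

    fitted = dict(zip(names, np.clip(sol.x, lo, hi)))
    resid = evaluate_residuals(problem, fitted, start_year, end_year)
    loss = _loss_from_residuals(resid)

    rank = None
    identifiable = None
    if sol.jac is not None and sol.jac.size:
        sv = np.linalg.svd(sol.jac, compute_uv=False)
        rank = int((sv > sv.max() * 1e-8).sum()) if sv.max() > 0 else 0
        identifiable = rank == len(free)

    return CalibrationResult(
        values=fitted, loss=loss, residuals=resid,
        converged=bool(sol.status > 0), message=sol.message,
        x0=x_start, nfev=int(sol.nfev),
        jacobian_rank=rank, identifiable=identifiable)


def _current_values(base: BaselineSetup, names: list[str]) -> np.ndarray:
    out = []
    for name in names:
        parts = name.split(":")
        kind = parts[0]
        if kind == "transition":
            out.append(base.params.transition[BAND_INDEX[parts[1]],
                                              TRANSITION_INDEX[parts[2]]])
        elif kind == "mortality":
            out.append(base.params.mortality[BAND_INDEX[parts[1]],
                                             STATE_INDEX[parts[2]]])
        elif kind == "ageing":
            out.append(base.params.ageing[BAND_INDEX[parts[1]]])
        elif kind == "entry_mix":
            out.append(base.params.entry_mix[STATE_INDEX[parts[1]]])
        elif kind == "initial":
            out.append(base.initial.counts[BAND_INDEX[parts[1]],
                                           STATE_INDEX[parts[2]]])
        elif kind == "entries":
            out.append(base.entries.entrants(int(parts[1])))
        elif kind == "service_rate":
            if base.service_rates is None:
                raise ValidationError("no service rates in baseline setup")
            out.append(base.service_rates.rates[
                BAND_INDEX[parts[1]], STATE_INDEX[parts[2]],
                CATEGORY_INDEX[parts[3]]])
        else:
            raise ValidationError(f"unknown parameter name {name!r}")
    return np.array(out, dtype=float)
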