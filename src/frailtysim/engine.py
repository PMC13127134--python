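"""Deterministic discrete-time stock-and-flow core.

One step advances the 16 compartments by one year. All outflows (death,
forward frailty transition, band promotion) are computed simultaneously from
start-of-year stocks and applied together; entrants turning 50 are added to
the youngest band afterwards, split by the entry mix. If a stratum's
per-capita outflow rates sum above 1, all of that stratum's rates are
rescaled by the reciprocal of the sum, which guarantees non-negative stocks
for any valid parameter set.

Because the rescaling depends only on the rates, every step is exactly an
affine map x' = M x + e * mix; :func:`build_affine_map` constructs (M, mix)
explicitly and serves as an independent oracle for :func:`step` /
:func:`run`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import EntrySchedule, ParameterSet, TRANSITIONS
from .structure import (
    AGE_BANDS,
    FRAILTY_STATES,
    N_BANDS,
    N_STATES,
    N_STRATA,
    PrevalenceResult,
    StockVector,
    ValidationError,
)

__all__ = [
    "FlowRecord",
    "Trajectory",
    "build_affine_map",
    "capped_outflow_rates",
    "step",
    "run",
    "annual_incidence",
    "prevalence",
]


def capped_outflow_rates(params: ParameterSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective per-capita outflow rates after proportional capping.

    Returns ``(death, transit, ageing)`` arrays, each shape (4, 4) indexed
    [band, state]. ``transit[b, s]`` is the rate of moving from state ``s``
    to ``s + 1`` within band ``b`` (zero for severe); ``ageing[b, s]`` the
    rate of promotion to band ``b + 1`` (zero for 85+). Where the three
    rates sum to s > 1 for a stratum they are jointly rescaled by 1/s.
    """
    death = params.mortality.copy()
    transit = np.zeros((N_BANDS, N_STATES))
    transit[:, :-1] = params.transition
    ageing = np.zeros((N_BANDS, N_STATES))
    ageing[:-1, :] = params.ageing[:, None]

    total = death + transit + ageing
    scale = np.where(total > 1.0, 1.0 / np.where(total > 0, total, 1.0), 1.0)
    return death * scale, transit * scale, ageing * scale


def build_affine_map(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """16x16 one-year update matrix and entry template for ``params``.

    The step is ``x(t+1) = M @ x(t) + entrants * template`` on band-major
    flattened stocks. Within each band the frailty block is lower
    triangular in frailty order (no recovery); the only off-band entries
    sit on the ageing superdiagonal (stratum i -> i + 4).
    """
    death, transit, ageing = capped_outflow_rates(params)
    M = np.zeros((N_STRATA, N_STRATA))
    for b in range(N_BANDS):
        for s in range(N_STATES):
            i = b * N_STATES + s
            M[i, i] = 1.0 - death[b, s] - transit[b, s] - ageing[b, s]
            if s + 1 < N_STATES:
                M[b * N_STATES + s + 1, i] = transit[b, s]
            if b + 1 < N_BANDS:
                M[(b + 1) * N_STATES + s, i] = ageing[b, s]
    template = np.zeros(N_STRATA)
    template[:N_STATES] = params.entry_mix
    return M, template


@dataclass(frozen=True)
class FlowRecord:
    """Person-flows during one simulated year (labelled by its start year).

    All entries are in persons and non-negative.
    """

    year: int
    incidence: np.ndarray        # (4,)  fit -> mild, per band
    progression: np.ndarray      # (4, 2) mild->moderate, moderate->severe per band
    deaths: np.ndarray           # (4, 4) per stratum
    ageing: np.ndarray           # (3, 4) band b -> b+1 promotions per state
    entries: np.ndarray          # (4,) entrants by frailty state

    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    def total_entries(self) -> float:
        return float(self.entries.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, band in enumerate(AGE_BANDS):
            for s, state in enumerate(FRAILTY_STATES):
                rows.append({
                    "year": self.year,
                    "age_band": band,
                    "frailty_state": state,
                    "deaths": self.deaths[b, s],
                    "transition_out": (
                        self.incidence[b] if s == 0
                        else self.progression[b, s - 1] if s in (1, 2)
                        else 0.0
                    ),
                    "ageing_out": self.ageing[b, s] if b < N_BANDS - 1 else 0.0,
                    "entries": self.entries[s] if b == 0 else 0.0,
                })
        return pd.DataFrame(rows)


def step(stocks: StockVector, params: ParameterSet,
         entrants_year: float) -> tuple[StockVector, FlowRecord]:
    """Advance the population by one year.

    Flows are computed simultaneously from start-of-year stocks; entrants
    are added to the 50-64 band (split by ``entry_mix``) after the flows.
    """
    if entrants_year < 0 or not np.isfinite(entrants_year):
        raise ValidationError(f"entrants must be finite and >= 0; got {entrants_year}")
    death_r, transit_r, ageing_r = capped_outflow_rates(params)
    x = stocks.counts

    deaths = x * death_r
    transit = x * transit_r            # [b, s]: flow s -> s+1 within band
    promoted = x * ageing_r            # [b, s]: flow band b -> b+1

    new = x - deaths - transit - promoted
    new[:, 1:] += transit[:, :-1]
    new[1:, :] += promoted[:-1, :]
    entries = entrants_year * params.entry_mix
    new[0, :] += entries

    # numerical guard: capping keeps outflow fractions <= 1, but rounding
    # can leave tiny negatives
    new = np.where(np.abs(new) < 1e-9, np.maximum(new, 0.0), new)

    record = FlowRecord(
        year=stocks.year,
        incidence=transit[:, 0].copy(),
        progression=transit[:, 1:3].copy(),
        deaths=deaths,
        ageing=promoted[:-1, :].copy(),
        entries=entries.copy(),
    )
    return StockVector(new, stocks.year + 1), record


@dataclass(frozen=True)
class Trajectory:
    """Stocks and flows of a multi-year run.

    Stocks are start-of-year values for every calendar year in
    ``[start_year, end_year]``; the flow ledger covers the steps
    ``start_year .. end_year - 1`` (each flow record transforms the stock of
    its year into the next year's stock). ``params_by_year`` is set when
    the run used year-varying parameters (one entry per stock year).
    """

    stocks: tuple[StockVector, ...]
    flows: tuple[FlowRecord, ...]
    params: ParameterSet
    params_by_year: tuple[ParameterSet, ...] | None = None

    def params_for(self, year: int) -> ParameterSet:
        if self.params_by_year is None:
            return self.params
        return self.params_by_year[year - self.start_year]

    @property
    def start_year(self) -> int:
        return self.stocks[0].year

    @property
    def end_year(self) -> int:
        return self.stocks[-1].year

    @property
    def years(self) -> list[int]:
        return [sv.year for sv in self.stocks]

    @property
    def horizon_years(self) -> int:
        """Number of simulated calendar years, inclusive of both ends."""
        return self.end_year - self.start_year + 1

    def stock(self, year: int) -> StockVector:
        if not (self.start_year <= year <= self.end_year):
            raise ValidationError(
                f"trajectory covers {self.start_year}-{self.end_year}; requested {year}"
            )
        return self.stocks[year - self.start_year]

    def stock_array(self) -> np.ndarray:
        """(n_years, 4, 4) array of stocks."""
        return np.stack([sv.counts for sv in self.stocks])

    def frail_series(self) -> pd.Series:
        return pd.Series(
            {sv.year: sv.frail_total() for sv in self.stocks}, name="frail")

    def total_series(self) -> pd.Series:
        return pd.Series(
            {sv.year: sv.total() for sv in self.stocks}, name="population")

    def moderate_severe_series(self) -> pd.Series:
        return pd.Series(
            {sv.year: float(sv.counts[:, 2:].sum()) for sv in self.stocks},
            name="moderate_severe")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (year, age_band, frailty_state).

        Stock plus the outflows/inflows of that year's step; flow columns
        are NaN for the final year, which has no recorded step.
        """
        stock_df = pd.concat([sv.to_frame() for sv in self.stocks], ignore_index=True)
        if self.flows:
            flow_df = pd.concat([fr.to_frame() for fr in self.flows], ignore_index=True)
            return stock_df.merge(flow_df, on=["year", "age_band", "frailty_state"],
                                  how="left")
        return stock_df


def run(initial: StockVector, params, entries: EntrySchedule,
        start_year: int, end_year: int) -> Trajectory:
    """Simulate from ``start_year`` to ``end_year`` inclusive.

    ``initial`` holds start-of-year stocks for ``start_year``; one step is
    taken per year in ``[start_year, end_year - 1]``, so the result has one
    stock vector per calendar year in the horizon. ``params`` is a
    :class:`~frailtysim.params.ParameterSet`, or a callable
    ``year -> ParameterSet`` for year-varying rates (e.g. ageing driven by
    explicit promotion schedules). Deterministic: the same inputs give
    bit-identical outputs.
    """
    if end_year < start_year:
        raise ValidationError("end_year must be >= start_year")
    if not entries.covers(start_year, end_year - 1):
        raise ValidationError(
            f"entry schedule ({entries.start_year}-{entries.end_year}) does not "
            f"cover simulated years {start_year}-{end_year - 1}"
        )
    if initial.year != start_year:
        initial = StockVector(initial.counts, start_year)

    varying = callable(params)
    params_fn = params if varying else (lambda _y: params)

    stocks = [initial]
    flows: list[FlowRecord] = []
    current = initial
    for year in range(start_year, end_year):
        current, record = step(current, params_fn(year), entries.entrants(year))
        stocks.append(current)
        flows.append(record)
    if varying:
        by_year = tuple(params_fn(y) for y in range(start_year, end_year + 1))
        return Trajectory(tuple(stocks), tuple(flows), by_year[-1], by_year)
    return Trajectory(tuple(stocks), tuple(flows), params)


def annual_incidence(traj: Trajectory, append_total: bool = True) -> pd.DataFrame:
    """New frailty cases (the fit -> mild flow) per year and age band.

    One row per stock year including the final one (whose flow is the
    fit -> mild rate applied to that year's start-of-year stock, exactly the
    arithmetic the ledger records for earlier years); an ``Overall`` column
    sums the bands, and a ``Total`` row sums the years when
    ``append_total``.
    """
    if not traj.stocks:
        raise ValidationError("trajectory is empty")
    rows = {}
    for sv in traj.stocks:
        _, transit_r, _ = capped_outflow_rates(traj.params_for(sv.year))
        rows[sv.year] = sv.counts[:, 0] * transit_r[:, 0]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(AGE_BANDS))
    df.index.name = "year"
    df["Overall"] = df.sum(axis=1)
    if append_total:
        df.loc["Total"] = df.sum(axis=0)
    return df


def prevalence(stocks: StockVector) -> PrevalenceResult:
    """Frailty prevalence of a stock vector.

    Raises
    ------
    ValidationError
        If the total population is zero (the fraction is undefined).
    """
    frail = stocks.frail_total()
    total = stocks.total()
    if total == 0:
        raise ValidationError("prevalence undefined for an empty population")
    return PrevalenceResult(frail, total, frail / total)
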