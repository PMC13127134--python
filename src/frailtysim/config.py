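"""Plain-text (YAML/JSON) configuration schema and round-trip I/O.

A run specification carries everything the pipeline needs: parameters,
initial stocks, entry schedule and (optionally) service rates and unit
costs. Files are YAML (JSON is a YAML subset and also accepted) with a
versioned ``schema_version``; validation is by pydantic, so a malformed
config reports every failing field with its location.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticError

from .params import EntrySchedule, ParameterSet, TRANSITIONS
from .services import SERVICE_CATEGORIES, ServiceRateSet, UnitCostSet
from .structure import AGE_BANDS, FRAILTY_STATES, StockVector, ValidationError

__all__ = ["SCHEMA_VERSION", "RunSpecification", "read_config", "write_config",
           "spec_from_objects"]

SCHEMA_VERSION = 1

BandMap = dict[str, float]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransitionCfg(_Strict):
    fit_mild: BandMap
    mild_moderate: BandMap
    moderate_severe: BandMap


class ParametersCfg(_Strict):
    transition: TransitionCfg
    mortality: dict[str, dict[str, float]]       # band -> state -> rate
    ageing: BandMap                               # closed bands only
    entry_mix: dict[str, float]                   # state -> share


class EntriesCfg(_Strict):
    start_year: int
    values: list[float] = Field(min_length=1)


class AgeingScheduleCfg(_Strict):
    """Optional year-varying band-promotion rates (one row of three closed-
    band rates per calendar year), overriding the constant ageing rates."""

    start_year: int
    values: list[list[float]] = Field(min_length=1)


class ServiceRatesCfg(_Strict):
    # band -> state -> category -> contacts per person-year
    rates: dict[str, dict[str, dict[str, float]]]


class UnitCostsCfg(_Strict):
    costs: dict[str, float]
    base_year: str = "2016/17"
    inflation_rate: float = 0.035


class RunSpecificationModel(_Strict):
    schema_version: int
    parameters: ParametersCfg
    initial_stocks: dict[str, dict[str, float]]   # band -> state -> persons
    initial_year: int
    entries: EntriesCfg
    ageing_schedule: Optional[AgeingScheduleCfg] = None
    service_rates: Optional[ServiceRatesCfg] = None
    unit_costs: Optional[UnitCostsCfg] = None


def _band_map_to_array(m: BandMap, bands: tuple[str, ...], what: str) -> np.ndarray:
    missing = [b for b in bands if b not in m]
    if missing:
        raise ValidationError(f"{what}: missing entries for {missing}")
    return np.array([m[b] for b in bands], dtype=float)


def _band_state_to_array(m: dict[str, dict[str, float]], what: str) -> np.ndarray:
    missing = [f"{b}/{s}" for b in AGE_BANDS for s in FRAILTY_STATES
               if s not in m.get(b, {})]
    if missing:
        raise ValidationError(f"{what}: missing entries for {missing}")
    return np.array([[m[b][s] for s in FRAILTY_STATES] for b in AGE_BANDS])


class RunSpecification:
    """A validated, ready-to-run model configuration."""

    def __init__(self, params: ParameterSet, initial: StockVector,
                 entries: EntrySchedule,
                 service_rates: ServiceRateSet | None = None,
                 unit_costs: UnitCostSet | None = None,
                 ageing_schedule: tuple[int, np.ndarray] | None = None):
        self.params = params
        self.initial = initial
        self.entries = entries
        self.service_rates = service_rates
        self.unit_costs = unit_costs
        self.ageing_schedule = ageing_schedule

    def engine_params(self):
        """Engine-ready parameters: a ParameterSet, or year -> ParameterSet
        when a year-varying ageing schedule is configured."""
        if self.ageing_schedule is None:
            return self.params
        start, sched = self.ageing_schedule

        def fn(year: int) -> ParameterSet:
            idx = min(max(year - start, 0), sched.shape[0] - 1)
            return self.params.with_(ageing=sched[idx])
        return fn


def _to_objects(model: RunSpecificationModel) -> RunSpecification:
    p = model.parameters
    transition = np.column_stack([
        _band_map_to_array(getattr(p.transition, tr), AGE_BANDS, f"transition.{tr}")
        for tr in TRANSITIONS
    ])
    mortality = _band_state_to_array(p.mortality, "mortality")
    ageing = _band_map_to_array(p.ageing, AGE_BANDS[:-1], "ageing")
    mix = np.array([p.entry_mix.get(s, None) for s in FRAILTY_STATES], dtype=object)
    if any(v is None for v in mix):
        missing = [s for s, v in zip(FRAILTY_STATES, mix) if v is None]
        raise ValidationError(f"entry_mix: missing entries for {missing}")
    params = ParameterSet(transition, mortality, ageing, mix.astype(float))

    initial = StockVector(
        _band_state_to_array(model.initial_stocks, "initial_stocks"),
        model.initial_year)
    entries = EntrySchedule(model.entries.start_year,
                            np.array(model.entries.values, dtype=float))

    rates = None
    if model.service_rates is not None:
        arr = np.zeros((len(AGE_BANDS), len(FRAILTY_STATES), len(SERVICE_CATEGORIES)))
        r = model.service_rates.rates
        missing = []
        for bi, b in enumerate(AGE_BANDS):
            for si, s in enumerate(FRAILTY_STATES):
                for ci, c in enumerate(SERVICE_CATEGORIES):
                    try:
                        arr[bi, si, ci] = r[b][s][c]
                    except KeyError:
                        missing.append(f"{b}/{s}/{c}")
        if missing:
            raise ValidationError(f"service_rates: missing entries for {missing}")
        rates = ServiceRateSet(arr)

    costs = None
    if model.unit_costs is not None:
        costs = UnitCostSet.from_dict(model.unit_costs.costs,
                                      base_year=model.unit_costs.base_year,
                                      inflation_rate=model.unit_costs.inflation_rate)

    sched = None
    if model.ageing_schedule is not None:
        arr = np.asarray(model.ageing_schedule.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(AGE_BANDS) - 1:
            raise ValidationError(
                "ageing_schedule rows must have one rate per closed band")
        sched = (model.ageing_schedule.start_year, arr)
    return RunSpecification(params, initial, entries, rates, costs, sched)


def read_config(path: str) -> RunSpecification:
    """Load and validate a run specification from a YAML/JSON file.

    Raises :class:`~frailtysim.structure.ValidationError` with every
    failing field named.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    try:
        model = RunSpecificationModel.model_validate(data)
    except PydanticError as exc:
        lines = [f"{path}: invalid configuration:"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"  - {loc}: {err['msg']}")
        raise ValidationError("\n".join(lines)) from exc
    if model.schema_version != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: unsupported schema_version {model.schema_version} "
            f"(expected {SCHEMA_VERSION})")
    return _to_objects(model)


def spec_to_dict(spec: RunSpecification) -> dict:
    p = spec.params
    d = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "transition": {
                tr: {b: float(p.transition[bi, ti])
                     for bi, b in enumerate(AGE_BANDS)}
                for ti, tr in enumerate(TRANSITIONS)
            },
            "mortality": {
                b: {s: float(p.mortality[bi, si])
                    for si, s in enumerate(FRAILTY_STATES)}
                for bi, b in enumerate(AGE_BANDS)
            },
            "ageing": {b: float(p.ageing[bi])
                       for bi, b in enumerate(AGE_BANDS[:-1])},
            "entry_mix": {s: float(p.entry_mix[si])
                          for si, s in enumerate(FRAILTY_STATES)},
        },
        "initial_stocks": {
            b: {s: float(spec.initial.counts[bi, si])
                for si, s in enumerate(FRAILTY_STATES)}
            for bi, b in enumerate(AGE_BANDS)
        },
        "initial_year": int(spec.initial.year),
        "entries": {
            "start_year": int(spec.entries.start_year),
            "values": [float(v) for v in spec.entries.values],
        },
    }
    if spec.ageing_schedule is not None:
        start, arr = spec.ageing_schedule
        d["ageing_schedule"] = {
            "start_year": int(start),
            "values": [[float(v) for v in row] for row in arr],
        }
    if spec.service_rates is not None:
        d["service_rates"] = {"rates": {
            b: {s: {c: float(spec.service_rates.rates[bi, si, ci])
                    for ci, c in enumerate(SERVICE_CATEGORIES)}
                for si, s in enumerate(FRAILTY_STATES)}
            for bi, b in enumerate(AGE_BANDS)
        }}
    if spec.unit_costs is not None:
        d["unit_costs"] = {
            "costs": {c: float(spec.unit_costs.costs[ci])
                      for ci, c in enumerate(SERVICE_CATEGORIES)},
            "base_year": spec.unit_costs.base_year,
            "inflation_rate": float(spec.unit_costs.inflation_rate),
        }
    return d


def write_config(spec: RunSpecification, path: str) -> None:
    """Write a run specification back to YAML (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def spec_from_objects(params: ParameterSet, initial: StockVector,
                      entries: EntrySchedule,
                      service_rates: ServiceRateSet | None = None,
                      unit_costs: UnitCostSet | None = None,
                      ageing_schedule: tuple[int, np.ndarray] | None = None,
                      ) -> RunSpecification:
    return RunSpecification(params, initial, entries, service_rates,
                            unit_costs, ageing_schedule)
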