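"""Service-use and cost overlay.

Annual per-person contact rates, specific to each of the 16 population
strata and nine service categories, are applied to start-of-year stocks to
produce contact counts; unit costs per contact then give costs. Outputs are
aggregated the way the projections are usually presented: by sector
(primary care vs secondary & urgent care) and by group (fit vs frail),
with contacts in millions and costs in GBP millions. Costs are reported at
base-year (2016/17) prices; the inflation helper exists only to harmonise
unit costs quoted against other base years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory
from .structure import N_BANDS, N_STATES, ValidationError

__all__ = [
    "SERVICE_CATEGORIES",
    "PRIMARY_CATEGORIES",
    "SECONDARY_CATEGORIES",
    "SECTORS",
    "category_sector",
    "ServiceRateSet",
    "UnitCostSet",
    "ContactSeries",
    "CostSeries",
    "project_contacts",
    "project_costs",
    "adjust_cost_base",
]

#: GP contact types (sector: primary care).
PRIMARY_CATEGORIES: tuple[str, ...] = (
    "gp_face_to_face", "gp_home_visit", "gp_telephone", "gp_econsult",
)
#: Hospital/urgent contact types (sector: secondary & urgent care).
SECONDARY_CATEGORIES: tuple[str, ...] = (
    "outpatient", "ed_attendance", "elective_admission",
    "unplanned_admission", "critical_care",
)
SERVICE_CATEGORIES: tuple[str, ...] = PRIMARY_CATEGORIES + SECONDARY_CATEGORIES
CATEGORY_INDEX = {c: i for i, c in enumerate(SERVICE_CATEGORIES)}
N_CATEGORIES = len(SERVICE_CATEGORIES)

SECTORS: tuple[str, ...] = ("primary", "secondary_urgent")

#: Reference inflation assumption for re-basing unit costs.
DEFAULT_INFLATION_RATE = 0.035
DEFAULT_COST_BASE_YEAR = "2016/17"

GROUPS: tuple[str, ...] = ("fit", "frail", "total")


def category_sector(category: str) -> str:
    if category in PRIMARY_CATEGORIES:
        return "primary"
    if category in SECONDARY_CATEGORIES:
        return "secondary_urgent"
    raise ValidationError(f"unknown service category {category!r}")


@dataclass(frozen=True)
class ServiceRateSet:
    """Annual contacts per person by (age band, frailty state, category).

    ``rates`` has shape (4, 4, 9) indexed [band, state, category] with the
    category order of :data:`SERVICE_CATEGORIES`; all entries finite, >= 0.
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.rates, dtype=float)
        if arr.shape != (N_BANDS, N_STATES, N_CATEGORIES):
            raise ValidationError(
                f"service rates must have shape {(N_BANDS, N_STATES, N_CATEGORIES)}; "
                f"got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("service rates contain non-finite values")
        if np.any(arr < 0):
            raise ValidationError("service rates must be >= 0")
        object.__setattr__(self, "rates", arr)
        arr.setflags(write=False)

    def category(self, name: str) -> np.ndarray:
        return self.rates[:, :, CATEGORY_INDEX[name]]

    def with_rates(self, rates: np.ndarray) -> "ServiceRateSet":
        return ServiceRateSet(rates)

    @classmethod
    def zeros(cls) -> "ServiceRateSet":
        return cls(np.zeros((N_BANDS, N_STATES, N_CATEGORIES)))


@dataclass(frozen=True)
class UnitCostSet:
    """Cost per contact in GBP for each service category, at a stated base.

    ``inflation_rate`` is used only by :func:`adjust_cost_base` when
    harmonising costs quoted against other base years.
    """

    costs: np.ndarray
    base_year: str = DEFAULT_COST_BASE_YEAR
    inflation_rate: float = DEFAULT_INFLATION_RATE

    def __post_init__(self) -> None:
        arr = np.asarray(self.costs, dtype=float)
        if arr.shape != (N_CATEGORIES,):
            raise ValidationError(
                f"unit costs must have shape {(N_CATEGORIES,)}; got {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError("unit costs must be finite and >= 0")
        if self.inflation_rate <= -1:
            raise ValidationError("inflation rate must be > -1")
        object.__setattr__(self, "costs", arr)
        arr.setflags(write=False)

    def cost(self, category: str) -> float:
        return float(self.costs[CATEGORY_INDEX[category]])

    @classmethod
    def from_dict(cls, mapping: dict[str, float], **kw) -> "UnitCostSet":
        missing = set(SERVICE_CATEGORIES) - set(mapping)
        if missing:
            raise ValidationError(f"unit costs missing categories: {sorted(missing)}")
        return cls(np.array([mapping[c] for c in SERVICE_CATEGORIES]), **kw)


def _aggregate(by_stratum: np.ndarray, years: list[int]) -> pd.DataFrame:
    """Aggregate (n_years, 4, 4, 9) values to year x (sector, group)."""
    n_primary = len(PRIMARY_CATEGORIES)
    out = {}
    for sector, sl in (("primary", slice(0, n_primary)),
                       ("secondary_urgent", slice(n_primary, N_CATEGORIES))):
        sec = by_stratum[:, :, :, sl].sum(axis=3)          # (years, band, state)
        fit = sec[:, :, 0].sum(axis=1)
        frail = sec[:, :, 1:].sum(axis=(1, 2))
        out[(sector, "fit")] = fit
        out[(sector, "frail")] = frail
        out[(sector, "total")] = fit + frail
    df = pd.DataFrame(out, index=pd.Index(years, name="year"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sector", "group"])
    return df


@dataclass(frozen=True)
class ContactSeries:
    """Per-year service contacts, resolved by stratum and category.

    ``by_stratum`` has shape (n_years, 4, 4, 9) in raw contacts;
    ``table`` aggregates to year x (sector, fit/frail/total) in raw
    contacts. Use :meth:`table_millions` for display.
    """

    years: tuple[int, ...]
    by_stratum: np.ndarray
    table: pd.DataFrame

    def category_totals(self, category: str) -> pd.Series:
        """Total contacts per year for one category (all strata)."""
        idx = CATEGORY_INDEX[category]
        return pd.Series(self.by_stratum[:, :, :, idx].sum(axis=(1, 2)),
                         index=list(self.years), name=category)

    def table_millions(self) -> pd.DataFrame:
        return self.table / 1e6


@dataclass(frozen=True)
class CostSeries:
    """Per-year costs in GBP, resolved by stratum and category.

    Same layout as :class:`ContactSeries`; ``table`` additionally carries a
    cross-sector ``("all", ...)`` block so the standard three-panel cost
    table (primary / secondary & urgent / total) can be read off directly.
    """

    years: tuple[int, ...]
    by_stratum: np.ndarray
    table: pd.DataFrame

    def total(self) -> pd.Series:
        return self.table[("all", "total")]

    def table_millions(self) -> pd.DataFrame:
        return self.table / 1e6


def project_contacts(traj: Trajectory, rates: ServiceRateSet) -> ContactSeries:
    """Apply per-person contact rates to every year's start-of-year stocks.

    ``contacts[year, b, s, c] = stock[year, b, s] * rates[b, s, c]``.
    """
    stocks = traj.stock_array()                      # (years, 4, 4)
    by_stratum = stocks[:, :, :, None] * rates.rates[None, :, :, :]
    years = traj.years
    return ContactSeries(tuple(years), by_stratum, _aggregate(by_stratum, years))


def project_costs(contacts: ContactSeries, unit_costs: UnitCostSet) -> CostSeries:
    """Cost each contact at its category's unit cost (base-year prices).

    No year-on-year inflation is applied: projections are reported in
    constant base-year GBP.
    """
    by_stratum = contacts.by_stratum * unit_costs.costs[None, None, None, :]
    table = _aggregate(by_stratum, list(contacts.years))
    for group in GROUPS:
        table[("all", group)] = (table[("primary", group)]
                                 + table[("secondary_urgent", group)])
    return CostSeries(contacts.years, by_stratum, table)


def adjust_cost_base(amount: float, from_year: int, to_year: int,
                     rate: float = DEFAULT_INFLATION_RATE) -> float:
    """Move an amount between cost base years at a constant inflation rate.

    ``amount * (1 + rate) ** (to_year - from_year)``; exact inverse when
    applied back, so re-basing round-trips.
    """
    if rate <= -1:
        raise ValidationError("inflation rate must be > -1")
    return float(amount) * (1.0 + rate) ** (to_year - from_year)
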