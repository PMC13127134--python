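"""Seeded synthetic inputs and packaged reference tables.

Everything stochastic in the package lives here: the engine itself is
deterministic, so parameter-recovery and property tests draw their inputs
from this module. Default magnitudes are chosen to put synthetic runs in
the regime of an ageing Western population with high measured frailty
prevalence (a prevalence plateau in the mid-70s percent range over a
16-year horizon); they are illustrative inputs, not estimates.

The packaged reference tables (projected incidence, contacts, costs and
headline scalar results) are shipped as versioned CSV and checked against
frozen SHA-256 digests on load.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .engine import Trajectory, run
from .params import DEFAULT_AGEING, EntrySchedule, ParameterSet
from .services import (
    ContactSeries,
    CostSeries,
    N_CATEGORIES,
    SERVICE_CATEGORIES,
    ServiceRateSet,
    UnitCostSet,
    project_contacts,
    project_costs,
)
from .structure import (
    AGE_BANDS,
    N_BANDS,
    N_STATES,
    StockVector,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "FixtureTables",
    "gen_parameter_set",
    "gen_initial_stocks",
    "gen_service_rates",
    "gen_unit_costs",
    "make_truth",
    "load_fixture_tables",
    "DEFAULT_INITIAL_MIX",
]

# Plausible stratum mix for a 50+ population with ~70% measured frailty:
# younger bands dominated by fit/mild, the oldest by moderate/severe.
# Rows are age bands (shares of total population), entries sum to 1.
DEFAULT_INITIAL_MIX = np.array([
    [0.2150, 0.1680, 0.0720, 0.0250],   # 50-64
    [0.0650, 0.0910, 0.0650, 0.0390],   # 65-74
    [0.0220, 0.0520, 0.0650, 0.0460],   # 75-84
    [0.0045, 0.0135, 0.0270, 0.0300],   # 85+
])
assert abs(DEFAULT_INITIAL_MIX.sum() - 1.0) < 1e-12


def _interval(lo: float, hi: float) -> tuple[float, float]:
    return (float(lo), float(hi))


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded ranges for every generated parameter family.

    All rate ranges are annual per-capita probabilities. ``age_gradient``
    sorts transition and mortality draws to be non-decreasing with age,
    the pattern seen in observed frailty data.
    """

    seed: int = 0
    fit_mild_range: tuple[float, float] = _interval(0.05, 0.12)
    mild_moderate_range: tuple[float, float] = _interval(0.03, 0.09)
    moderate_severe_range: tuple[float, float] = _interval(0.02, 0.08)
    mortality_band_ranges: tuple[tuple[float, float], ...] = (
        _interval(0.002, 0.010),   # 50-64
        _interval(0.008, 0.030),   # 65-74
        _interval(0.025, 0.080),   # 75-84
        _interval(0.080, 0.250),   # 85+
    )
    frailty_mortality_spread: float = 1.8   # severe/fit mortality ratio
    ageing_rates: tuple[float, ...] = tuple(DEFAULT_AGEING)
    entry_mix_mean: tuple[float, ...] = (0.55, 0.30, 0.10, 0.05)
    entry_mix_concentration: float = 200.0
    entrants_range: tuple[float, float] = _interval(6.0e5, 8.0e5)
    total_population: float = 23.1e6
    initial_mix: np.ndarray = field(
        default_factory=lambda: DEFAULT_INITIAL_MIX.copy())
    primary_rate_fit_range: tuple[float, float] = _interval(3.0, 7.0)
    primary_rate_frail_range: tuple[float, float] = _interval(8.0, 18.0)
    secondary_rate_fit_range: tuple[float, float] = _interval(1.0, 3.0)
    secondary_rate_frail_range: tuple[float, float] = _interval(3.5, 8.0)
    unit_cost_jitter: float = 0.10
    age_gradient: bool = True

    def __post_init__(self) -> None:
        mix = np.asarray(self.initial_mix, dtype=float)
        if mix.shape != (N_BANDS, N_STATES):
            raise ValidationError("initial_mix must have shape (4, 4)")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("initial_mix must be a simplex over the 16 strata")
        for name in ("fit_mild_range", "mild_moderate_range",
                     "moderate_severe_range", "entrants_range",
                     "primary_rate_fit_range", "primary_rate_frail_range",
                     "secondary_rate_fit_range", "secondary_rate_frail_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValidationError(f"invalid range for {name}: ({lo}, {hi})")
        for lo, hi in self.mortality_band_ranges:
            if not (0 <= lo <= hi <= 1):
                raise ValidationError("mortality ranges must satisfy 0 <= lo <= hi <= 1")
        object.__setattr__(self, "initial_mix", mix)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw(rng: np.random.Generator, lo: float, hi: float, size=None) -> np.ndarray:
    if lo == hi:   # degenerate range: exact requested value
        return np.full(size, lo) if size is not None else np.float64(lo)
    return rng.uniform(lo, hi, size)


def gen_parameter_set(cfg: GeneratorConfig) -> ParameterSet:
    """Draw an annual-rate parameter set within the configured ranges."""
    rng = cfg.rng()
    transition = np.column_stack([
        _draw(rng, *cfg.fit_mild_range, N_BANDS),
        _draw(rng, *cfg.mild_moderate_range, N_BANDS),
        _draw(rng, *cfg.moderate_severe_range, N_BANDS),
    ])
    if cfg.age_gradient:
        transition = np.sort(transition, axis=0)

    mortality = np.empty((N_BANDS, N_STATES))
    for b, (lo, hi) in enumerate(cfg.mortality_band_ranges):
        base = _draw(rng, lo, hi)
        # frailty gradient within the band, capped at 1
        spread = np.linspace(1.0, cfg.frailty_mortality_spread, N_STATES)
        mortality[b] = np.minimum(base * spread, 1.0)
    if cfg.age_gradient:
        mortality = np.sort(mortality, axis=0)

    mix_mean = np.asarray(cfg.entry_mix_mean, dtype=float)
    mix = rng.dirichlet(mix_mean * cfg.entry_mix_concentration)
    mix = mix / mix.sum()

    return ParameterSet(
        transition=np.clip(transition, 0.0, 1.0),
        mortality=np.clip(mortality, 0.0, 1.0),
        ageing=np.asarray(cfg.ageing_rates, dtype=float),
        entry_mix=mix,
    )


def gen_initial_stocks(cfg: GeneratorConfig, year: int = 2025) -> StockVector:
    """Initial stocks = total population x configured stratum mix."""
    if cfg.total_population < 0:
        raise ValidationError("total_population must be >= 0")
    return StockVector(cfg.total_population * cfg.initial_mix, year)


def gen_entry_schedule(cfg: GeneratorConfig, start_year: int,
                       end_year: int) -> EntrySchedule:
    rng = np.random.default_rng(cfg.seed + 1)
    n = max(end_year - start_year + 1, 1)
    return EntrySchedule(start_year, _draw(rng, *cfg.entrants_range, n))


# Representative 2016/17-era unit costs per contact, GBP.
DEFAULT_UNIT_COSTS = {
    "gp_face_to_face": 38.0,
    "gp_home_visit": 77.0,
    "gp_telephone": 15.0,
    "gp_econsult": 8.0,
    "outpatient": 125.0,
    "ed_attendance": 160.0,
    "elective_admission": 3749.0,
    "unplanned_admission": 1609.0,
    "critical_care": 1932.0,
}

# Within-sector category shares used to split a generated per-person
# sector rate into the nine service categories.
_PRIMARY_SHARES = np.array([0.62, 0.08, 0.25, 0.05])
_SECONDARY_SHARES = np.array([0.70, 0.15, 0.05, 0.08, 0.02])


def gen_service_rates(cfg: GeneratorConfig) -> ServiceRateSet:
    """Per-person contact rates, graded by frailty (frail >> fit)."""
    rng = np.random.default_rng(cfg.seed + 2)
    rates = np.zeros((N_BANDS, N_STATES, N_CATEGORIES))
    frail_weight = np.linspace(0.0, 1.0, N_STATES)   # fit..severe
    for b in range(N_BANDS):
        p_fit = _draw(rng, *cfg.primary_rate_fit_range)
        p_frail = _draw(rng, *cfg.primary_rate_frail_range)
        s_fit = _draw(rng, *cfg.secondary_rate_fit_range)
        s_frail = _draw(rng, *cfg.secondary_rate_frail_range)
        for s in range(N_STATES):
            w = frail_weight[s]
            rates[b, s, :4] = (p_fit + w * (p_frail - p_fit)) * _PRIMARY_SHARES
            rates[b, s, 4:] = (s_fit + w * (s_frail - s_fit)) * _SECONDARY_SHARES
    return ServiceRateSet(rates)


def gen_unit_costs(cfg: GeneratorConfig) -> UnitCostSet:
    """Representative unit costs with a seeded multiplicative jitter."""
    rng = np.random.default_rng(cfg.seed + 3)
    base = np.array([DEFAULT_UNIT_COSTS[c] for c in SERVICE_CATEGORIES])
    jitter = rng.uniform(1 - cfg.unit_cost_jitter, 1 + cfg.unit_cost_jitter,
                         base.size) if cfg.unit_cost_jitter else 1.0
    return UnitCostSet(base * jitter)


@dataclass(frozen=True)
class SyntheticTruth:
    """A fully generated model world plus the observables it implies."""

    params: ParameterSet
    initial: StockVector
    entries: EntrySchedule
    service_rates: ServiceRateSet
    unit_costs: UnitCostSet
    trajectory: Trajectory
    contacts: ContactSeries
    costs: CostSeries


def make_truth(cfg: GeneratorConfig, start_year: int = 2025,
               end_year: int = 2040) -> SyntheticTruth:
    """Generate parameters and run the real engine on them.

    The returned observables (trajectory, contacts, costs) serve as
    noiseless calibration targets whose generating parameters are known.
    """
    params = gen_parameter_set(cfg)
    initial = gen_initial_stocks(cfg, start_year)
    entries = gen_entry_schedule(cfg, start_year, max(end_year - 1, start_year))
    rates = gen_service_rates(cfg)
    unit_costs = gen_unit_costs(cfg)
    traj = run(initial, params, entries, start_year, end_year)
    contacts = project_contacts(traj, rates)
    costs = project_costs(contacts, unit_costs)
    return SyntheticTruth(params, initial, entries, rates, unit_costs,
                          traj, contacts, costs)


# --------------------------------------------------------------------------
# Packaged reference tables
# --------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    "table1_incidence.csv": "b1a13303119b2032937848cb2f143118026de5c31dfd3a9f4414073e643b52fe",
    "table1_totals.csv": "010db7c33c72c062871253e8c0664e7cad6d0592b982930a5421738936f40f73",
    "table2_contacts.csv": "3039aecd54d56c327e43f31f60418c684c5b152e994db69fa1bfba12eaef1ba8",
    "table3_costs.csv": "c297ffc1889f275ad1ebd266c8b670dcee6f92d0dbc24d3d74679646edbb5ed9",
    "result_scalars.csv": "0ce0e0b77887d39c44d0f3bd49b3604c4a72d9832983538a171ec4617c99493f",
}


@dataclass(frozen=True)
class FixtureTables:
    """Machine-readable copies of the published projection tables.

    ``incidence``: year x band (persons, as printed, plus ``overall``);
    ``incidence_totals``: printed column totals (kept exactly as printed —
    the 65-74 total differs from the rounded annual sum by 9 persons
    because the source totals were computed before rounding);
    ``contacts``: year x sector/group in millions; ``costs``: year x
    sector/group in GBP millions; ``scalars``: headline published results
    keyed by name, with a provenance column in the underlying CSV.
    """

    incidence: pd.DataFrame
    incidence_totals: pd.Series
    contacts: pd.DataFrame
    costs: pd.DataFrame
    scalars: pd.Series
    scalar_sources: pd.Series


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("frailtysim.data").joinpath(name)
    raw = ref.read_bytes()
    expected = _FIXTURE_SHA256[name]
    digest = hashlib.sha256(raw).hexdigest()
    if expected is not None and digest != expected:
        raise ValidationError(
            f"packaged fixture {name} is corrupted "
            f"(sha256 {digest}, expected {expected})")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw), comment="#")


def load_fixture_tables() -> FixtureTables:
    """Load and integrity-check the packaged reference tables."""
    t1 = _read_fixture("table1_incidence.csv").set_index("year")
    totals = _read_fixture("table1_totals.csv").set_index("column")["total"]
    t2 = _read_fixture("table2_contacts.csv").set_index("year")
    t3 = _read_fixture("table3_costs.csv").set_index("year")
    sc = _read_fixture("result_scalars.csv").set_index("name")
    return FixtureTables(
        incidence=t1,
        incidence_totals=totals,
        contacts=t2,
        costs=t3,
        scalars=sc["value"].astype(float),
        scalar_sources=sc["source"],
    )
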