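"""Annual rate parameters and entry schedules for the population engine.

All rates are per-capita annual probabilities in [0, 1]. Frailty can only
deteriorate (fit -> mild -> moderate -> severe); there are structurally no
reverse-transition parameters. People age along the band chain at a
band-promotion rate, die at an age- and frailty-specific mortality rate, and
new 50-year-olds enter the youngest band each year, split across frailty
states by an entry mix.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structure import (
    AGE_BANDS,
    BAND_INDEX,
    BAND_WIDTHS,
    FRAILTY_STATES,
    N_BANDS,
    N_STATES,
    STATE_INDEX,
    ValidationError,
    _as_band_state_array,
)

#: The three forward transitions, in severity order.
TRANSITIONS: tuple[str, ...] = ("fit_mild", "mild_moderate", "moderate_severe")
TRANSITION_INDEX = {t: i for i, t in enumerate(TRANSITIONS)}
N_TRANSITIONS = len(TRANSITIONS)

#: Default band-promotion rates: 1/width for each closed band. The open-ended
#: 85+ band has no ageing outflow (exit only by death).
DEFAULT_AGEING = np.array([1.0 / w for w in BAND_WIDTHS if w is not None])

ENTRY_MIX_TOL = 1e-12


def _check_unit_interval(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    """All annual per-capita rates governing the population flows.

    Parameters
    ----------
    transition
        Shape (4, 3): ``transition[band, k]`` for k in
        (fit->mild, mild->moderate, moderate->severe).
    mortality
        Shape (4, 4): ``mortality[band, state]``.
    ageing
        Shape (3,): band-promotion rate for the three closed bands.
    entry_mix
        Shape (4,): simplex over frailty states for persons entering at 50.
    """

    transition: np.ndarray
    mortality: np.ndarray
    ageing: np.ndarray
    entry_mix: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.transition, dtype=float)
        if tr.shape != (N_BANDS, N_TRANSITIONS):
            raise ValidationError(
                f"transition must have shape {(N_BANDS, N_TRANSITIONS)}; got {tr.shape}"
            )
        mo = _as_band_state_array(self.mortality, "mortality")
        ag = np.asarray(self.ageing, dtype=float)
        if ag.shape != (N_BANDS - 1,):
            raise ValidationError(
                f"ageing must have shape {(N_BANDS - 1,)} (closed bands only); got {ag.shape}"
            )
        mix = np.asarray(self.entry_mix, dtype=float)
        if mix.shape != (N_STATES,):
            raise ValidationError(f"entry_mix must have shape {(N_STATES,)}; got {mix.shape}")
        for arr, name in ((tr, "transition"), (mo, "mortality"),
                          (ag, "ageing"), (mix, "entry_mix")):
            _check_unit_interval(arr, name)
        if abs(mix.sum() - 1.0) > ENTRY_MIX_TOL:
            raise ValidationError(
                f"entry_mix must sum to 1 within {ENTRY_MIX_TOL}; got {mix.sum()!r}"
            )
        for name, arr in (("transition", tr), ("mortality", mo),
                          ("ageing", ag), ("entry_mix", mix)):
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)

    # -- convenience accessors --------------------------------------------
    def transition_rate(self, band: str, kind: str) -> float:
        return float(self.transition[BAND_INDEX[band], TRANSITION_INDEX[kind]])

    def mortality_rate(self, band: str, state: str) -> float:
        return float(self.mortality[BAND_INDEX[band], STATE_INDEX[state]])

    def with_(self, **kwargs) -> "ParameterSet":
        """Copy with some arrays replaced (arrays are re-validated)."""
        return replace(self, **kwargs)

    @classmethod
    def zeros(cls) -> "ParameterSet":
        """All-zero rates with an all-fit entry mix (identity dynamics)."""
        mix = np.zeros(N_STATES)
        mix[0] = 1.0
        return cls(
            transition=np.zeros((N_BANDS, N_TRANSITIONS)),
            mortality=np.zeros((N_BANDS, N_STATES)),
            ageing=np.zeros(N_BANDS - 1),
            entry_mix=mix,
        )


@dataclass(frozen=True)
class EntrySchedule:
    """Persons turning 50 (entering the model) per calendar year.

    ``values[i]`` is the number of entrants during calendar year
    ``start_year + i``.
    """

    start_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValidationError("entry schedule must be a non-empty 1-d array")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValidationError("entrants must be finite and non-negative")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)

    @property
    def end_year(self) -> int:
        """Last calendar year covered (inclusive)."""
        return self.start_year + self.values.size - 1

    def covers(self, start_year: int, end_year: int) -> bool:
        """True if every year in [start_year, end_year] has an entry count.

        An empty range (end_year < start_year) is trivially covered.
        """
        if end_year < start_year:
            return True
        return self.start_year <= start_year and end_year <= self.end_year

    def entrants(self, year: int) -> float:
        if not (self.start_year <= year <= self.end_year):
            raise ValidationError(
                f"entry schedule covers {self.start_year}-{self.end_year}; "
                f"requested {year}"
            )
        return float(self.values[year - self.start_year])

    @classmethod
    def constant(cls, start_year: int, end_year: int, per_year: float) -> "EntrySchedule":
        n = end_year - start_year + 1
        return cls(start_year, np.full(max(n, 1), float(per_year)))
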