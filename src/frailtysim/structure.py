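"""Population structure: age bands, frailty states and the stock vector.

The model population (adults aged 50 and over) is stratified into four age
bands crossed with four electronic-Frailty-Index (eFI) categories, giving 16
compartments ("stocks"). Arrays throughout the package are indexed
``[age_band, frailty_state]`` with the orderings below.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Age bands, ordered. Only the last band is open-ended.
AGE_BANDS: tuple[str, ...] = ("50-64", "65-74", "75-84", "85+")

#: Width of each closed band in years (None = open-ended).
BAND_WIDTHS: tuple[int | None, ...] = (15, 10, 10, None)

#: Frailty categories in order of increasing severity.
FRAILTY_STATES: tuple[str, ...] = ("fit", "mild", "moderate", "severe")

#: eFI score intervals defining each category (half-open; documentation only —
#: the simulation operates on categories, never raw scores).
EFI_RANGES: dict[str, tuple[float, float]] = {
    "fit": (0.0, 0.12),
    "mild": (0.12, 0.24),
    "moderate": (0.24, 0.36),
    "severe": (0.36, float("inf")),
}

N_BANDS = len(AGE_BANDS)
N_STATES = len(FRAILTY_STATES)
N_STRATA = N_BANDS * N_STATES

BAND_INDEX = {b: i for i, b in enumerate(AGE_BANDS)}
STATE_INDEX = {s: i for i, s in enumerate(FRAILTY_STATES)}

#: Frail = any category above fit.
FRAIL_STATES: tuple[str, ...] = FRAILTY_STATES[1:]


def stratum_index(band: str, state: str) -> int:
    """Flat index of a (band, state) stratum in band-major order."""
    return BAND_INDEX[band] * N_STATES + STATE_INDEX[state]


def stratum_labels() -> list[tuple[str, str]]:
    """All 16 (band, state) pairs in flat (band-major) order."""
    return [(b, s) for b in AGE_BANDS for s in FRAILTY_STATES]


class ValidationError(ValueError):
    """Raised when model inputs violate their structural invariants."""


def _as_band_state_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_BANDS, N_STATES):
        raise ValidationError(
            f"{name} must have shape {(N_BANDS, N_STATES)} "
            f"[age_band, frailty_state]; got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class StockVector:
    """Person counts in the 16 age x frailty compartments at one time point.

    Parameters
    ----------
    counts
        Array of shape (4, 4), ``counts[band, state]`` persons; must be
        finite and non-negative.
    year
        Calendar year the counts refer to (start of year).
    """

    counts: np.ndarray
    year: int

    def __post_init__(self) -> None:
        arr = _as_band_state_array(self.counts, "stocks")
        if np.any(arr < 0):
            raise ValidationError("stocks must be non-negative")
        object.__setattr__(self, "counts", arr)
        arr.setflags(write=False)

    # -- accessors ---------------------------------------------------------
    def get(self, band: str, state: str) -> float:
        return float(self.counts[BAND_INDEX[band], STATE_INDEX[state]])

    def total(self) -> float:
        return float(self.counts.sum())

    def band_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def state_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frail_total(self) -> float:
        """Persons in any frailty category (mild + moderate + severe)."""
        return float(self.counts[:, 1:].sum())

    def flat(self) -> np.ndarray:
        """Counts flattened in band-major order (matches the affine map)."""
        return self.counts.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray, year: int) -> "StockVector":
        return cls(np.asarray(flat, dtype=float).reshape(N_BANDS, N_STATES), year)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-stratum representation."""
        rows = [
            {"year": self.year, "age_band": b, "frailty_state": s,
             "stock": self.get(b, s)}
            for b, s in stratum_labels()
        ]
        return pd.DataFrame(rows)

    def replace_counts(self, counts: np.ndarray, year: int | None = None) -> "StockVector":
        return StockVector(counts, self.year if year is None else year)


@dataclass(frozen=True)
class PrevalenceResult:
    """Frailty prevalence at a time point."""

    frail_count: float
    total_count: float
    frail_fraction: float

    fields = ("frail_count", "total_count", "frail_fraction")

    def __iter__(self):
        return iter((self.frail_count, self.total_count, self.frail_fraction))
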