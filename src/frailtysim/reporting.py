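"""Derived summary statistics, display rounding and run outputs.

All statistics are computed from raw (unrounded) series and rounded only
at display, half-up (the convention the reference tables appear to use):
percentages and GBP bn to 1 decimal place, GBP m to the nearest million.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .engine import annual_incidence, prevalence
from .scenarios import ComparisonReport, PipelineOutputs
from .structure import ValidationError

__all__ = [
    "round_half_up",
    "growth_pct",
    "SummaryStats",
    "summarize",
    "write_outputs",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Unlike :func:`round`, 0.5 at the last kept digit always rounds up
    (2.35 -> 2.4), matching how printed health-economics tables are
    usually rounded.
    """
    if not np.isfinite(x):
        return float(x)
    q = 10.0 ** ndigits
    return float(np.floor(np.abs(x) * q + 0.5) / q * np.sign(x)) if x else 0.0


def growth_pct(start: float, end: float, ndigits: int = 1) -> float:
    """Percentage growth 100 * (end - start) / start, rounded half-up."""
    if start == 0:
        raise ValidationError("growth undefined for a zero start value")
    return round_half_up(100.0 * (end - start) / start, ndigits)


@dataclass(frozen=True)
class ScenarioSummary:
    name: str
    annual_saving_gbp_m: float
    cumulative_saving_gbp_bn: float
    frail_delta_final_year: float
    moderate_severe_delta_final_year: float


@dataclass(frozen=True)
class SummaryStats:
    """Headline statistics of a baseline run plus scenario comparisons.

    Percentages and GBP bn are rounded half-up to 1 dp, savings per annum
    to the nearest GBP million; the prevalence series is in percent at
    1 dp per year.
    """

    start_year: int
    end_year: int
    population_start: float
    population_end: float
    population_growth_pct: float
    frail_start: float
    frail_end: float
    frail_growth_pct: float
    prevalence_pct: dict[int, float]
    total_cost_start_gbp_m: float
    total_cost_end_gbp_m: float
    total_cost_change_gbp_bn: float
    frail_cost_change_gbp_bn: float
    total_new_cases: float
    scenarios: tuple[ScenarioSummary, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = [asdict(s) for s in self.scenarios]
        return d


def summarize(base: PipelineOutputs,
              scenario_reports: dict[str, ComparisonReport] | None = None,
              ) -> SummaryStats:
    """Headline statistics from raw pipeline outputs.

    All inputs stay unrounded until the final display rounding.
    """
    traj = base.trajectory
    pop = traj.total_series()
    frail = traj.frail_series()
    start, end = traj.start_year, traj.end_year

    prev = {
        int(sv.year): round_half_up(100.0 * prevalence(sv).frail_fraction, 1)
        for sv in traj.stocks
    }

    total_cost = base.costs.table[("all", "total")]
    frail_cost = base.costs.table[("all", "frail")]
    inc = annual_incidence(traj, append_total=False)

    scen_summaries = []
    for name, report in (scenario_reports or {}).items():
        scen_summaries.append(ScenarioSummary(
            name=name,
            annual_saving_gbp_m=round_half_up(report.average_annual_saving / 1e6, 0),
            cumulative_saving_gbp_bn=round_half_up(report.cumulative_saving / 1e9, 2),
            frail_delta_final_year=float(report.frail_delta.iloc[-1]),
            moderate_severe_delta_final_year=float(
                report.moderate_severe_delta.iloc[-1]),
        ))

    return SummaryStats(
        start_year=start,
        end_year=end,
        population_start=float(pop.loc[start]),
        population_end=float(pop.loc[end]),
        population_growth_pct=growth_pct(pop.loc[start], pop.loc[end]),
        frail_start=float(frail.loc[start]),
        frail_end=float(frail.loc[end]),
        frail_growth_pct=growth_pct(frail.loc[start], frail.loc[end]),
        prevalence_pct=prev,
        total_cost_start_gbp_m=float(total_cost.loc[start]) / 1e6,
        total_cost_end_gbp_m=float(total_cost.loc[end]) / 1e6,
        total_cost_change_gbp_bn=round_half_up(
            (total_cost.loc[end] - total_cost.loc[start]) / 1e9, 1),
        frail_cost_change_gbp_bn=round_half_up(
            (frail_cost.loc[end] - frail_cost.loc[start]) / 1e9, 1),
        total_new_cases=float(inc["Overall"].sum()),
        scenarios=tuple(scen_summaries),
    )


# --------------------------------------------------------------------------
# Run outputs
# --------------------------------------------------------------------------

def _sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(outputs: PipelineOutputs, out_dir: str,
                  summary: SummaryStats | None = None,
                  reports: dict[str, ComparisonReport] | None = None,
                  input_paths: list[str] | None = None) -> dict:
    """Write a run's outputs as tidy CSV/JSON plus a manifest.

    Files are written atomically (temp file + rename). The manifest
    records input hashes, package version and a timestamp; rerunning with
    unchanged inputs reproduces every file byte-for-byte except the
    manifest timestamp.
    """
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _atomic_write(name: str, writer) -> str:
        path = os.path.join(out_dir, name)
        tmp = path + ".tmp"
        writer(tmp)
        os.replace(tmp, path)
        written.append(path)
        return path

    _atomic_write("trajectory.csv",
                  lambda p: outputs.trajectory.to_frame().to_csv(p, index=False))
    _atomic_write("contacts.csv",
                  lambda p: outputs.contacts.table_millions().to_csv(p))
    _atomic_write("costs.csv",
                  lambda p: outputs.costs.table_millions().to_csv(p))
    _atomic_write("incidence.csv",
                  lambda p: annual_incidence(outputs.trajectory).to_csv(p))
    if summary is not None:
        _atomic_write("summary.json", lambda p: _dump_json(summary.to_dict(), p))
    for name, report in (reports or {}).items():
        _atomic_write(f"scenario_{name}_costs_delta.csv",
                      lambda p, r=report: r.costs_delta.to_csv(p))
        _atomic_write(f"scenario_{name}_summary.json",
                      lambda p, r=report: _dump_json(r.summary(), p))

    manifest = {
        "package": "frailtysim",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {p: _sha256_of(p) for p in (input_paths or [])},
        "outputs": {os.path.basename(p): _sha256_of(p) for p in written},
    }
    _atomic_write("manifest.json", lambda p: _dump_json(manifest, p))
    return manifest


def _dump_json(obj: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
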