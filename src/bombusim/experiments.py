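"""Scenario grid, replicate orchestration and summary statistics.

The experiment crosses the handling-time engine with foraging mortality:
one ``ORG`` scenario (mechanistic Harder engine, high mortality — the model
default) plus the full cross of {LOW, MED, HIGH} mortality ×
{112.5, 225, 450, 900, 1800, 3600} s fixed handling time, 19 scenarios in
all, named ``MORTALITY_HANDLINGTIME`` (e.g. ``MED_450``).

Each scenario × replicate runs on the same landscape (regenerated fresh
from the same seed, as all scenarios share one map) with a replicate seed
derived from the master seed, the scenario name and the replicate index.
Summaries per run: trip-count-weighted mean nectar and pollen trip
durations, end-of-run queen count (the December-31 population proxy) and
the mean daily colony count over the last three years.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .colony import BeeSpecies, ColonyParams, DEFAULT_BEE
from .handling import HandlingConfig
from .landscape import LandscapeSpec, generate_landscape
from .mortality import mortality_rate
from .simulator import DailyMetrics, SimulationResult, run_simulation

__all__ = [
    "FIXED_HANDLING_LEVELS",
    "ScenarioConfig",
    "build_scenario_grid",
    "weighted_mean_trip_duration",
    "hibernating_queens_at_end",
    "mean_colonies_last_years",
    "replicate_seed",
    "run_scenario",
    "run_experiment",
    "SUMMARY_COLUMNS",
]

FIXED_HANDLING_LEVELS = (112.5, 225.0, 450.0, 900.0, 1800.0, 3600.0)

_MORT_LABEL = {"low": "LOW", "intermediate": "MED", "high": "HIGH"}
_LABEL_MORT = {v: k for k, v in _MORT_LABEL.items()}


@dataclass(frozen=True)
class ScenarioConfig:
    """One row of the scenario grid."""

    name: str
    fixed_handling_enabled: bool
    fixed_handling_time_s: Optional[float]
    mortality_model: str

    def __post_init__(self) -> None:
        mortality_rate(self.mortality_model)  # validates the name
        if (self.name == "ORG") != (not self.fixed_handling_enabled):
            raise ValueError('name "ORG" must coincide with the fixed engine being off')
        if self.fixed_handling_enabled:
            if self.fixed_handling_time_s is None or self.fixed_handling_time_s <= 0:
                raise ValueError("fixed_handling_time_s must be > 0")

    def handling_config(self, **kwargs) -> HandlingConfig:
        if self.fixed_handling_enabled:
            return HandlingConfig(
                fixed_handling_enabled=True,
                fixed_handling_time_s=float(self.fixed_handling_time_s),
                **kwargs,
            )
        return HandlingConfig(fixed_handling_enabled=False, **kwargs)


def _level_label(value: float) -> str:
    return str(int(value))  # 112.5 -> "112", matching the scenario syntax


def build_scenario_grid() -> list[ScenarioConfig]:
    """The 19-scenario grid: ORG plus {LOW, MED, HIGH} × six fixed values."""
    grid = [ScenarioConfig("ORG", False, None, "high")]
    for mort in ("low", "intermediate", "high"):
        for value in FIXED_HANDLING_LEVELS:
            grid.append(
                ScenarioConfig(
                    name=f"{_MORT_LABEL[mort]}_{_level_label(value)}",
                    fixed_handling_enabled=True,
                    fixed_handling_time_s=value,
                    mortality_model=mort,
                )
            )
    return grid


def scenario_by_name(name: str) -> ScenarioConfig:
    for s in build_scenario_grid():
        if s.name == name:
            return s
    valid = ", ".join(s.name for s in build_scenario_grid())
    raise ValueError(f"unknown scenario {name!r}; valid: {valid}")


def weighted_mean_trip_duration(daily: Iterable[tuple[float, int]]) -> float:
    """Trip-count-weighted mean of daily mean durations.

    Σ(mean_d · n_d) / Σ n_d over days with n_d > 0; equals the grand mean
    of all individual trips. Zero total trips is undefined and raises.
    """
    num = 0.0
    den = 0
    for mean_s, n in daily:
        if n > 0:
            num += mean_s * n
            den += n
    if den == 0:
        raise ValueError("no trips: weighted mean trip duration is undefined")
    return num / den


def hibernating_queens_at_end(metrics: Sequence[DailyMetrics]) -> int:
    """Queen census on the final timestep (December 31) — population proxy."""
    if not metrics:
        raise ValueError("empty run")
    return metrics[-1].n_queens


def mean_colonies_last_years(metrics: Sequence[DailyMetrics], years: int = 3) -> float:
    """Mean daily colony count over the last ``years`` × 365 timesteps."""
    n = min(len(metrics), years * 365)
    return float(np.mean([m.n_colonies for m in metrics[-n:]]))


def replicate_seed(master_seed: int, scenario_name: str, replicate: int) -> np.random.SeedSequence:
    """Audit-stable replicate seed: hash of (master seed, scenario, index)."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(scenario_name.encode()), int(replicate)]
    )


def _weighted_or_nan(metrics: Sequence[DailyMetrics], kind: str) -> tuple[float, int]:
    if kind == "nectar":
        pairs = [(m.mean_nectar_trip_s, m.n_nectar_trips) for m in metrics
                 if m.n_nectar_trips > 0]
    else:
        pairs = [(m.mean_pollen_trip_s, m.n_pollen_trips) for m in metrics
                 if m.n_pollen_trips > 0]
    n = sum(p[1] for p in pairs)
    if n == 0:
        return float("nan"), 0
    return weighted_mean_trip_duration(pairs), n


def run_scenario(
    scenario: ScenarioConfig,
    landscape_spec: LandscapeSpec = LandscapeSpec(),
    years: int = 5,
    seed: int | np.random.SeedSequence = 0,
    initial_queens: int = 100,
    bee: BeeSpecies = DEFAULT_BEE,
    params: ColonyParams = ColonyParams(),
    record_trips: bool = False,
) -> SimulationResult:
    """Run one scenario once on a freshly generated landscape."""
    land = generate_landscape(landscape_spec)
    return run_simulation(
        landscape=land,
        handling=scenario.handling_config(),
        mortality_model=scenario.mortality_model,
        years=years,
        seed=seed,
        initial_queens=initial_queens,
        bee=bee,
        params=params,
        record_trips=record_trips,
    )


SUMMARY_COLUMNS = [
    "scenario", "replicate", "seed",
    "mean_nectar_trip_s", "mean_pollen_trip_s",
    "n_nectar_trips", "n_pollen_trips",
    "end_queens", "mean_colonies_last3y",
]


def run_experiment(
    grid: Sequence[ScenarioConfig] | None = None,
    replicates: int = 20,
    master_seed: int = 0,
    landscape_spec: LandscapeSpec = LandscapeSpec(),
    years: int = 5,
    initial_queens: int = 100,
    bee: BeeSpecies = DEFAULT_BEE,
    params: ColonyParams = ColonyParams(),
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario × replicate; returns the summary table.

    Deterministic given ``master_seed``: replicate seeds derive from
    (master seed, scenario name, replicate index) and are recorded in the
    ``seed`` column for audit.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = build_scenario_grid() if grid is None else list(grid)
    rows = []
    for sc in grid:
        for rep in range(replicates):
            ss = replicate_seed(master_seed, sc.name, rep)
            seed_int = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            res = run_scenario(
                sc, landscape_spec=landscape_spec, years=years,
                seed=np.random.SeedSequence(seed_int),
                initial_queens=initial_queens, bee=bee, params=params,
            )
            mn, nn = _weighted_or_nan(res.metrics, "nectar")
            mp, np_ = _weighted_or_nan(res.metrics, "pollen")
            rows.append({
                "scenario": sc.name,
                "replicate": rep,
                "seed": seed_int,
                "mean_nectar_trip_s": mn,
                "mean_pollen_trip_s": mp,
                "n_nectar_trips": nn,
                "n_pollen_trips": np_,
                "end_queens": hibernating_queens_at_end(res.metrics),
                "mean_colonies_last3y": mean_colonies_last_years(res.metrics),
            })
            if progress:
                print(f"{sc.name} rep {rep}: end_queens={rows[-1]['end_queens']}")
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
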