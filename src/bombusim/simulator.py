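"""The daily simulation loop: calendar, agent scheduling, metric recording.

Years are 365 days (no leap days), so a 5-year run is exactly 1825 daily
timesteps starting on January 1. Each day: patches replenish, free-living
queens act (wake, search, found), colonies act in a freshly randomised
order, and the day's census and trip statistics are recorded. On December
31 the overwinter survival lottery is applied to the queens produced that
year. Extinction (no living queen and no living colony) is absorbing.

All randomness flows from one seed through named, independent streams
(placement, emergence, nest search, foraging mortality, exploration, trait
draws, scheduling order), so adding a draw to one process never shifts the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .colony import (
    BeeSpecies,
    Colony,
    ColonyParams,
    DEFAULT_BEE,
    Queen,
    TripRecord,
    colony_daily_step,
    queen_daily_step,
)
from .flora import Landscape
from .handling import ForagerTraits, HandlingConfig
from .mortality import mortality_rate

__all__ = ["DailyMetrics", "SimulationResult", "run_simulation"]


@dataclass(frozen=True)
class DailyMetrics:
    """One row of the daily output: censuses, trip counts and mean durations.

    Mean durations are ``None`` on days without the corresponding trips.
    """

    day: int
    n_queens: int
    n_colonies: int
    n_nectar_trips: int
    n_pollen_trips: int
    mean_nectar_trip_s: Optional[float]
    mean_pollen_trip_s: Optional[float]


@dataclass
class SimulationResult:
    metrics: list[DailyMetrics]
    trips: Optional[list[TripRecord]]
    total_nectar_collected_ul: float       # by surviving (delivering) trips
    total_nectar_inflow_ul: float          # credited to colony stores
    total_pollen_collected_g: float
    total_pollen_inflow_g: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([m.__dict__ for m in self.metrics])


def _validate_scenario(handling: HandlingConfig, mortality_model: str) -> float:
    rate = mortality_rate(mortality_model)  # raises on unknown name
    if handling.fixed_handling_enabled and not (handling.fixed_handling_time_s > 0):
        raise ValueError("fixed_handling_time_s must be > 0 when the fixed engine is on")
    return rate


def run_simulation(
    landscape: Landscape,
    handling: HandlingConfig,
    mortality_model: str = "high",
    years: int = 5,
    seed: int | np.random.SeedSequence = 0,
    initial_queens: int = 100,
    bee: BeeSpecies = DEFAULT_BEE,
    params: ColonyParams = ColonyParams(),
    record_trips: bool = False,
) -> SimulationResult:
    """Run the colony/population model and return daily metrics.

    ``landscape`` is mutated during the run (stocks); pass a fresh or
    re-generated landscape per replicate. Fully reproducible given
    ``seed``: two runs from the same seed produce identical outputs.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if landscape.n_patches == 0:
        raise ValueError("landscape must contain at least one patch")
    mort_rate = _validate_scenario(handling, mortality_model)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    (ss_place, ss_emerge, ss_nest, ss_mort, ss_explore, ss_traits, ss_order) = ss.spawn(7)
    rng_place = np.random.default_rng(ss_place)
    rng_emerge = np.random.default_rng(ss_emerge)
    rng_nest = np.random.default_rng(ss_nest)
    rng_mort = np.random.default_rng(ss_mort)
    rng_explore = np.random.default_rng(ss_explore)
    rng_traits = np.random.default_rng(ss_traits)
    rng_order = np.random.default_rng(ss_order)

    extent_x = float(landscape.x.max()) if landscape.n_patches else 0.0
    extent_y = float(landscape.y.max()) if landscape.n_patches else 0.0

    def new_queen(qid: int, x: float, y: float, birth_year: int) -> Queen:
        g = rng_traits.uniform(bee.glossa_min_mm, bee.glossa_max_mm)
        doy = int(rng_emerge.integers(bee.emergence_start_doy, bee.emergence_end_doy + 1))
        return Queen(
            id=qid,
            traits=ForagerTraits(glossa_mm=g, weight_g=bee.weight_g),
            x=x,
            y=y,
            emergence_doy=doy,
            birth_year=birth_year,
        )

    next_qid = 0
    queens: list[Queen] = []
    for _ in range(initial_queens):
        x = rng_place.uniform(0.0, max(extent_x, 1.0))
        y = rng_place.uniform(0.0, max(extent_y, 1.0))
        queens.append(new_queen(next_qid, x, y, birth_year=0))
        next_qid += 1

    colonies: list[Colony] = []
    next_cid = 0
    nesting_idx = np.flatnonzero(landscape.is_nesting)

    metrics: list[DailyMetrics] = []
    trip_log: list[TripRecord] = [] if record_trips else None
    tot_nc = tot_ni = tot_pc = tot_pi = 0.0

    total_days = years * 365
    for day in range(1, total_days + 1):
        doy = (day - 1) % 365 + 1
        year = (day - 1) // 365 + 1
        landscape.replenish_all(doy)
        day_trips: list[TripRecord] = []

        in_season = doy <= params.season_end_doy
        if in_season and queens:
            order = rng_order.permutation(len(queens))
            for qi in order:
                q = queens[qi]
                if q.state == "hibernating" and q.birth_year >= year:
                    continue  # produced this year; sleeps until next spring
                free = landscape.nest_site_capacity - sum(c.alive for c in colonies)
                event = queen_daily_step(q, doy, free, params, rng_nest)
                if event == "founded":
                    if nesting_idx.size == 0:
                        q.set_state("dead")
                        continue
                    site = int(nesting_idx[rng_nest.integers(nesting_idx.size)])
                    col = Colony(
                        id=next_cid,
                        queen=q,
                        nest_patch_idx=site,
                        x=float(landscape.x[site]),
                        y=float(landscape.y[site]),
                        n_patches=landscape.n_patches,
                        nectar_store_ul=params.founder_initial_store_ul,
                        founded_day=day,
                    )
                    col.attach(landscape)
                    next_cid += 1
                    colonies.append(col)

        if in_season and colonies:
            order = rng_order.permutation(len(colonies))
            for ci in order:
                col = colonies[ci]
                if not col.alive:
                    continue
                trips, n_new = colony_daily_step(
                    col, landscape, day, doy, handling, bee, mort_rate,
                    params, rng_mort, rng_explore, rng_traits,
                )
                day_trips.extend(trips)
                for _ in range(n_new):
                    queens.append(new_queen(next_qid, col.x, col.y, birth_year=year))
                    next_qid += 1

        if doy == params.season_end_doy:
            for col in colonies:
                if col.alive:
                    col.alive = False
                    col.queen.state = "dead"
            for q in queens:
                if q.state == "searching":
                    q.state = "dead"

        if doy == 365:
            # overwinter survival of this year's hibernating queens
            for q in queens:
                if q.state == "hibernating" and q.birth_year == year:
                    if rng_emerge.random() >= params.p_overwinter:
                        q.state = "dead"

        # prune and record
        queens = [q for q in queens if q.state != "dead"]
        for c in colonies:
            if not c.alive:
                tot_ni += c.nectar_inflow_ul
                tot_pi += c.pollen_inflow_g
        colonies = [c for c in colonies if c.alive]

        for t in day_trips:
            if t.type == "nectar":
                tot_nc += 0.0 if t.forager_died else t.collected
            else:
                tot_pc += 0.0 if t.forager_died else t.collected
        if record_trips:
            trip_log.extend(day_trips)

        n_trips = [t.duration_s for t in day_trips if t.type == "nectar"]
        p_trips = [t.duration_s for t in day_trips if t.type == "pollen"]
        metrics.append(
            DailyMetrics(
                day=day,
                n_queens=len(queens),
                n_colonies=len(colonies),
                n_nectar_trips=len(n_trips),
                n_pollen_trips=len(p_trips),
                mean_nectar_trip_s=(sum(n_trips) / len(n_trips)) if n_trips else None,
                mean_pollen_trip_s=(sum(p_trips) / len(p_trips)) if p_trips else None,
            )
        )

    for c in colonies:  # colonies still alive at the end of the run
        tot_ni += c.nectar_inflow_ul
        tot_pi += c.pollen_inflow_g
    return SimulationResult(
        metrics=metrics,
        trips=trip_log,
        total_nectar_collected_ul=tot_nc,
        total_nectar_inflow_ul=tot_ni,
        total_pollen_collected_g=tot_pc,
        total_pollen_inflow_g=tot_pi,
    )
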