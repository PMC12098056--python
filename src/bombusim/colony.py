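"""Colony-level agents: queens, colonies, foragers and their daily behaviour.

The life cycle is a deliberately compact surrogate for the full
individual-based bumblebee model it emulates: queens wake from hibernation
in spring, search for a nest site in a nesting habitat (hedgerow/scrub),
found a colony, forage alone until the first workers emerge, after which
workers forage under a daily time budget; from mid-July the colony converts
its nectar surplus into new queens, which hibernate and — if they survive
the winter — repeat the cycle next year.

Energetics are the binding constraint. Nectar (µl) is the single energy
currency: adults and larvae consume fixed daily amounts, and *foraging
itself costs nectar* at ``forage_cost_ul_per_s`` per second of trip time
(default 0.06 µl/s, i.e. roughly a 0.6 W flight metabolic rate fuelled by
nectar at ~10 J/µl). A 120 µl crop load therefore nets nothing once a trip
exceeds ~2000 s — which is why very long handling times starve colonies
regardless of how low the foraging mortality is.

Foragers pick patches by expected intake rate (expected load over expected
trip duration at the patch's current filling level), choosing among
memorised patches plus an occasional exploratory candidate, and give up for
the day when the best rate drops below a floor (near-empty landscape).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as _Path
from typing import Optional

import numpy as np
import pandas as pd

from .flora import Landscape
from .handling import ForagerTraits, HandlingConfig, harder_th_array
from .mortality import trip_survival

__all__ = [
    "BeeSpecies",
    "ColonyParams",
    "Queen",
    "Forager",
    "Colony",
    "TripRecord",
    "PatchChoice",
    "select_patch",
    "nectar_trip",
    "pollen_trip",
    "colony_daily_step",
    "queen_daily_step",
    "produce_sexuals",
    "read_bee_table",
    "write_bee_table",
    "BEE_COLUMNS",
    "DEFAULT_BEE",
]

BEE_COLUMNS = [
    "name",
    "glossa_min_mm",
    "glossa_max_mm",
    "weight_g",
    "crop_capacity_ul",
    "emergence_start_doy",
    "emergence_end_doy",
]


@dataclass(frozen=True)
class BeeSpecies:
    """Bee-species parameters; glossa length is drawn uniformly per individual."""

    name: str = "bombus_terrestris"
    glossa_min_mm: float = 6.9
    glossa_max_mm: float = 11.1
    weight_g: float = 0.195
    crop_capacity_ul: float = 120.0
    emergence_start_doy: int = 60   # Mar 1
    emergence_end_doy: int = 105    # Apr 15

    def __post_init__(self) -> None:
        if not (0 < self.glossa_min_mm <= self.glossa_max_mm):
            raise ValueError("glossa range must satisfy 0 < min <= max")
        if self.weight_g <= 0 or self.crop_capacity_ul <= 0:
            raise ValueError("weight and crop capacity must be > 0")
        if not (1 <= self.emergence_start_doy <= self.emergence_end_doy <= 365):
            raise ValueError("emergence window must lie in [1, 365], start <= end")


@dataclass(frozen=True)
class ColonyParams:
    """Behavioural and energetic constants of the simplified life cycle.

    All values are configuration-exposed; units in the field names.
    """

    daily_budget_s: float = 28800.0          # 8 h forageable time per worker
    founder_budget_s: float = 14400.0        # founding queens also incubate
    adult_nectar_ul_day: float = 40.0
    queen_nectar_ul_day: float = 60.0
    larva_nectar_ul_day: float = 20.0
    larva_pollen_g_day: float = 0.004
    dev_days: int = 28                       # egg -> worker, aggregated
    worker_lifespan_days: int = 30
    eggs_base: float = 2.0
    eggs_per_worker: float = 0.5
    max_eggs_per_day: int = 2
    switch_doy: int = 196                    # Jul 15: worker -> sexual production
    season_end_doy: int = 304                # Oct 31: all colony activity stops
    starvation_days: int = 2
    cost_per_queen_ul: float = 1200.0
    p_overwinter: float = 0.3
    p_nest_daily: float = 0.2
    exploration_prob: float = 0.1
    forage_cost_ul_per_s: float = 0.06       # nectar burned per second of trip
    min_nectar_rate_ul_s: float = 0.01       # give-up intake-rate floor
    min_pollen_rate_g_s: float = 1e-5
    pollen_handling_base_s: float = 300.0
    pollen_load_g: float = 0.1
    reserve_days: float = 3.0
    founder_initial_store_ul: float = 100.0
    queens_per_worker_day: float = 0.05      # queen-rearing capacity of the workforce


QUEEN_STATES = ("hibernating", "searching", "founding", "producing", "dead")


@dataclass
class Queen:
    id: int
    traits: ForagerTraits
    x: float
    y: float
    emergence_doy: int
    birth_year: int = 0
    state: str = "hibernating"

    def set_state(self, new: str) -> None:
        if self.state == "dead":
            raise ValueError("no resurrection: queen is dead")
        if new not in QUEEN_STATES:
            raise ValueError(f"unknown queen state {new!r}")
        self.state = new


@dataclass
class Forager:
    glossa_mm: float
    age_days: int = 0
    # per-landscape static handling terms, cached lazily (see harder_static)
    handling_static: Optional[tuple] = field(default=None, repr=False, compare=False)


def harder_static(
    land: Landscape, traits: ForagerTraits, crop_ul: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patch handling terms that do not depend on the filling level:
    (Tt + Ta, Ti, Nflowers). Ti is inf at/past the corolla/glossa pole."""
    G, W = traits.glossa_mm, traits.weight_g
    ta = 0.3 + 0.04 * land.corolla_depth
    frac = 1.0 - land.corolla_depth / G
    base = 0.3 * W ** (1.0 / 3.0) * G ** 1.41
    arg = np.where(frac > 0, base * np.maximum(frac, 0.0) ** 0.4, 0.0)
    ti = np.full(arg.shape, np.inf)
    ok = arg > 1.0
    ti[ok] = np.log10(land.nectar_volume[ok] + 1.0) / np.log10(arg[ok]) - 0.3 * ta[ok] + 1.0
    ti[ti <= 0] = np.inf
    n = np.maximum(1, np.ceil(crop_ul / land.nectar_volume))
    return ta + land.interflower_travel, ti, n


@dataclass
class TripRecord:
    day: int
    type: str               # "nectar" | "pollen"
    duration_s: float
    patch_id: int
    collected: float        # µl (nectar) or g (pollen)
    forager_died: bool


@dataclass
class Colony:
    id: int
    queen: Queen
    nest_patch_idx: int
    x: float
    y: float
    n_patches: int
    nectar_store_ul: float = 0.0
    pollen_store_g: float = 0.0
    workers: list[Forager] = field(default_factory=list)
    brood_ages: list[int] = field(default_factory=list)
    queens_produced: int = 0
    alive: bool = True
    starve_streak: int = 0
    founded_day: int = 0
    # bookkeeping for conservation checks
    nectar_inflow_ul: float = 0.0
    pollen_inflow_g: float = 0.0

    def __post_init__(self) -> None:
        # memory of successfully foraged patches and last observed intake rate
        self.memory = np.zeros(self.n_patches, dtype=bool)
        self.last_rate = np.zeros(self.n_patches, dtype=float)
        self.dist: Optional[np.ndarray] = None  # filled on attach to landscape

    @property
    def n_workers(self) -> int:
        return len(self.workers)

    @property
    def n_brood(self) -> int:
        return len(self.brood_ages)

    def attach(self, land: Landscape) -> None:
        self.dist = land.distances_from(self.x, self.y)


@dataclass(frozen=True)
class PatchChoice:
    """A selected patch with its expected trip numbers (at selection-time γ)."""

    idx: int
    duration_s: float
    expected_amount: float
    rate: float


def _th_for_candidates(
    land: Landscape,
    cand: np.ndarray,
    gamma: np.ndarray,
    engine_cfg: HandlingConfig,
    traits: ForagerTraits,
    crop_ul: float,
    static: Optional[tuple] = None,
) -> np.ndarray:
    # gamma > 0 for every candidate (candidates require positive stock)
    if engine_cfg.fixed_handling_enabled:
        return np.minimum(engine_cfg.fixed_handling_time_s / gamma, engine_cfg.t_max_s)
    if static is None:
        return harder_th_array(
            land.interflower_travel[cand],
            land.corolla_depth[cand],
            land.nectar_volume[cand],
            gamma,
            traits,
            crop_ul,
            engine_cfg.t_max_s,
        )
    tt_ta, ti, n = static
    return np.minimum((tt_ta[cand] / gamma + ti[cand]) * n[cand], engine_cfg.t_max_s)


def select_patch(
    colony: Colony,
    land: Landscape,
    engine_cfg: HandlingConfig,
    traits: ForagerTraits,
    params: ColonyParams,
    rng: np.random.Generator,
    resource: str = "nectar",
    crop_ul: float | None = None,
    static: Optional[tuple] = None,
) -> Optional[PatchChoice]:
    """Choose the patch maximising expected intake rate.

    Candidates are the colony's memorised patches with positive stock, plus
    (with probability ``exploration_prob``, or always when no memorised
    candidate exists) one uniformly random unmemorised stocked patch. Ties
    break to the lowest patch id. Returns None when nothing is stocked or
    the best expected rate falls below the give-up floor.
    """
    if resource == "nectar":
        stock = land.nectar_stock
        cap = land.nectar_capacity
        load = crop_ul if crop_ul is not None else engine_cfg.crop_capacity_ul
        floor = params.min_nectar_rate_ul_s
    else:
        stock = land.pollen_stock
        cap = land.pollen_capacity
        load = params.pollen_load_g
        floor = params.min_pollen_rate_g_s

    stocked = stock > 0
    mem_cand = np.flatnonzero(colony.memory & stocked)
    cand = mem_cand
    unmem = np.flatnonzero(~colony.memory & stocked)
    if unmem.size and (mem_cand.size == 0 or rng.random() < params.exploration_prob):
        extra = unmem[rng.integers(unmem.size)]
        cand = np.sort(np.append(mem_cand, extra))
    if cand.size == 0:
        return None

    gamma = stock[cand] / cap[cand]  # cap > 0 wherever stock > 0
    if resource == "nectar":
        th = _th_for_candidates(land, cand, gamma, engine_cfg, traits, load, static)
    else:
        th = np.minimum(params.pollen_handling_base_s / gamma, engine_cfg.t_max_s)
    dur = 2.0 * colony.dist[cand] / engine_cfg.flight_speed_m_s + th
    amount = np.minimum(load, stock[cand])
    rate = amount / dur
    best = int(np.argmax(rate))  # first max -> lowest patch id (cand sorted)
    if rate[best] < floor:
        return None
    return PatchChoice(
        idx=int(cand[best]),
        duration_s=float(dur[best]),
        expected_amount=float(amount[best]),
        rate=float(rate[best]),
    )


def nectar_trip(
    colony: Colony,
    traits: ForagerTraits,
    choice: PatchChoice,
    mort_rate: float,
    rng: np.random.Generator,
    land: Landscape,
    params: ColonyParams,
    day: int,
    crop_ul: float,
) -> TripRecord:
    """Execute one nectar trip to an already-selected patch.

    The patch is depleted whether or not the forager survives the trip home
    (death strikes en route back); only survivors deliver their load. The
    trip's metabolic nectar cost is charged to the colony store on survival.
    """
    F = choice.duration_s
    collected = land.deplete_nectar(choice.idx, crop_ul)
    died = rng.random() >= trip_survival(mort_rate, F)
    if not died:
        colony.nectar_store_ul += collected
        colony.nectar_inflow_ul += collected
        colony.nectar_store_ul -= params.forage_cost_ul_per_s * F
        colony.memory[choice.idx] = True
        colony.last_rate[choice.idx] = collected / F
    return TripRecord(day, "nectar", F, int(land.patch_id[choice.idx]), collected, died)


def pollen_trip(
    colony: Colony,
    traits: ForagerTraits,
    choice: PatchChoice,
    mort_rate: float,
    rng: np.random.Generator,
    land: Landscape,
    params: ColonyParams,
    day: int,
) -> TripRecord:
    """Execute one pollen trip (fixed base handling scaled by pollen filling
    level and capped at Tmax; untouched by the nectar handling engine)."""
    F = choice.duration_s
    collected = land.deplete_pollen(choice.idx, params.pollen_load_g)
    died = rng.random() >= trip_survival(mort_rate, F)
    if not died:
        colony.pollen_store_g += collected
        colony.pollen_inflow_g += collected
        colony.nectar_store_ul -= params.forage_cost_ul_per_s * F
        colony.memory[choice.idx] = True
        colony.last_rate[choice.idx] = collected / F
    return TripRecord(day, "pollen", F, int(land.patch_id[choice.idx]), collected, died)


def _targets(colony: Colony, params: ColonyParams, doy: int) -> tuple[float, float]:
    daily_need = (
        colony.n_workers * params.adult_nectar_ul_day
        + params.queen_nectar_ul_day
        + colony.n_brood * params.larva_nectar_ul_day
    )
    nectar_target = params.reserve_days * daily_need
    if doy >= params.switch_doy:
        # hoard provisions for the queen larvae in rearing; rearing capacity
        # scales with the workforce (fractions carry over in the store)
        hoard = (params.cost_per_queen_ul * params.queens_per_worker_day
                 * colony.n_workers)
        nectar_target += hoard
    pollen_target = params.reserve_days * colony.n_brood * params.larva_pollen_g_day
    if colony.n_brood == 0 and doy < params.switch_doy:
        pollen_target = params.larva_pollen_g_day * params.reserve_days  # seed stock
    return nectar_target, pollen_target


def produce_sexuals(colony: Colony, doy: int, params: ColonyParams) -> int:
    """Convert nectar surplus into new queens (one per ``cost_per_queen_ul``).

    Runs only from ``switch_doy``; daily production is bounded by the worker
    population (rearing capacity). Returns the number of queens produced.
    """
    if doy < params.switch_doy or not colony.alive:
        return 0
    reserve = params.reserve_days * (
        colony.n_workers * params.adult_nectar_ul_day
        + params.queen_nectar_ul_day
        + colony.n_brood * params.larva_nectar_ul_day
    )
    surplus = colony.nectar_store_ul - reserve
    if surplus < params.cost_per_queen_ul:
        return 0
    k = min(int(surplus // params.cost_per_queen_ul), colony.n_workers)
    if k <= 0:
        return 0
    colony.nectar_store_ul -= k * params.cost_per_queen_ul
    colony.queens_produced += k
    return k


def colony_daily_step(
    colony: Colony,
    land: Landscape,
    day: int,
    doy: int,
    engine_cfg: HandlingConfig,
    bee: BeeSpecies,
    mort_rate: float,
    params: ColonyParams,
    rng_mort: np.random.Generator,
    rng_explore: np.random.Generator,
    rng_traits: np.random.Generator,
    trips_out: Optional[list[TripRecord]] = None,
) -> tuple[list[TripRecord], int]:
    """One day of colony life; returns (trips, new sexual queens produced).

    Order: forage (demand-driven, per-forager time budget) → sexual
    production harvests the surplus → adult consumption and starvation
    accounting → brood feeding (culling what cannot be fed) →
    development/emergence → egg laying → ageing and lifespan deaths.
    """
    trips: list[TripRecord] = trips_out if trips_out is not None else []
    if not colony.alive:
        return trips, 0
    crop = bee.crop_capacity_ul
    n_before = len(trips)

    mechanistic = not engine_cfg.fixed_handling_enabled
    founder_phase = colony.n_workers == 0
    if founder_phase:
        if mechanistic and getattr(colony, "_founder_static", None) is None:
            colony._founder_static = harder_static(land, colony.queen.traits, crop)
        roster = [(colony.queen.traits, params.founder_budget_s, None,
                   getattr(colony, "_founder_static", None))]
    else:
        roster = []
        for w in colony.workers:
            traits = ForagerTraits(w.glossa_mm, bee.weight_g)
            if mechanistic and w.handling_static is None:
                w.handling_static = harder_static(land, traits, crop)
            roster.append((traits, params.daily_budget_s, w, w.handling_static))

    nectar_target, pollen_target = _targets(colony, params, doy)
    landscape_bare = {"nectar": False, "pollen": False}
    for traits, budget, worker, static in roster:
        remaining = budget
        while True:
            nd = (max(0.0, nectar_target - colony.nectar_store_ul) / nectar_target
                  if nectar_target > 0 else 0.0)
            pdf = (max(0.0, pollen_target - colony.pollen_store_g) / pollen_target
                   if pollen_target > 0 else 0.0)
            if nd <= 0 and pdf <= 0:
                break
            order = ["nectar", "pollen"] if nd >= pdf else ["pollen", "nectar"]
            choice = None
            resource = None
            for res in order:
                deficit = nd if res == "nectar" else pdf
                if deficit <= 0 or landscape_bare[res]:
                    continue
                choice = select_patch(
                    colony, land, engine_cfg, traits, params, rng_explore,
                    resource=res, crop_ul=crop, static=static,
                )
                if choice is not None:
                    resource = res
                    break
                landscape_bare[res] = True
            if choice is None or choice.duration_s > remaining:
                break
            remaining -= choice.duration_s
            if resource == "nectar":
                rec = nectar_trip(colony, traits, choice, mort_rate, rng_mort,
                                  land, params, day, crop)
            else:
                rec = pollen_trip(colony, traits, choice, mort_rate, rng_mort,
                                  land, params, day)
            trips.append(rec)
            # a fresh collection may re-open a previously bare resource
            landscape_bare = {"nectar": False, "pollen": False}
            if rec.forager_died:
                if worker is None:
                    colony.queen.set_state("dead")
                    colony.alive = False
                    return (trips[n_before:] if trips_out is not None else trips), 0
                colony.workers.remove(worker)
                break
        if not colony.alive:
            break

    # --- sexual production harvests the surplus at peak store, before the
    # day's consumption erodes it --------------------------------------------
    new_queens = produce_sexuals(colony, doy, params)

    # --- adult consumption (survival precedes brood care) -------------------
    need = colony.n_workers * params.adult_nectar_ul_day + params.queen_nectar_ul_day
    if colony.nectar_store_ul >= need:
        colony.nectar_store_ul -= need
        colony.starve_streak = 0
    else:
        colony.nectar_store_ul = 0.0
        colony.starve_streak += 1

    # --- brood feeding (cull what cannot be fed today) ---------------------
    n_larvae = colony.n_brood
    if n_larvae:
        affordable = min(
            n_larvae,
            int(colony.nectar_store_ul // params.larva_nectar_ul_day),
            int(colony.pollen_store_g // params.larva_pollen_g_day),
        )
        if affordable < n_larvae:
            colony.brood_ages.sort()
            colony.brood_ages = colony.brood_ages[n_larvae - affordable:]  # keep oldest
        colony.nectar_store_ul -= affordable * params.larva_nectar_ul_day
        colony.pollen_store_g -= affordable * params.larva_pollen_g_day

    # --- development and emergence -----------------------------------------
    colony.brood_ages = [a + 1 for a in colony.brood_ages]
    emerging = sum(1 for a in colony.brood_ages if a >= params.dev_days)
    if emerging:
        colony.brood_ages = [a for a in colony.brood_ages if a < params.dev_days]
        for _ in range(emerging):
            g = rng_traits.uniform(bee.glossa_min_mm, bee.glossa_max_mm)
            colony.workers.append(Forager(glossa_mm=g, age_days=0))

    # --- egg laying ---------------------------------------------------------
    # stimulated by nectar stores: a colony holding a comfortable maintenance
    # reserve lays at full rate, a depleted one backs off, so brood demand
    # tracks what the surrounding landscape actually supports; workers are
    # reared through autumn to sustain the foraging force of the sexual phase
    daily_need = (colony.n_workers * params.adult_nectar_ul_day
                  + params.queen_nectar_ul_day
                  + colony.n_brood * params.larva_nectar_ul_day)
    comfort = max(daily_need, (params.reserve_days - 1.0) * daily_need)
    fullness = min(1.0, colony.nectar_store_ul / comfort) if comfort > 0 else 0.0
    eggs = int(min(params.max_eggs_per_day,
                   params.eggs_base + params.eggs_per_worker * colony.n_workers)
               * fullness)
    colony.brood_ages.extend([0] * eggs)

    colony.pollen_store_g = max(0.0, colony.pollen_store_g)

    # --- ageing -------------------------------------------------------------
    for w in colony.workers:
        w.age_days += 1
    colony.workers = [w for w in colony.workers if w.age_days < params.worker_lifespan_days]

    if colony.starve_streak >= params.starvation_days:
        colony.alive = False
        colony.queen.state = "dead"
    return trips[n_before:] if trips_out is not None else trips, new_queens


def queen_daily_step(
    queen: Queen,
    doy: int,
    free_nest_sites: int,
    params: ColonyParams,
    rng_nest: np.random.Generator,
) -> str:
    """Advance a free-living queen one day; returns an event label.

    Hibernating queens wake on their emergence day; searching queens found a
    colony with daily probability ``p_nest_daily`` provided a nest site is
    free (the landscape caps simultaneous colonies).
    """
    if queen.state == "dead":
        return "none"
    if queen.state == "hibernating":
        if doy >= queen.emergence_doy:
            queen.set_state("searching")
            return "emerged"
        return "none"
    if queen.state == "searching":
        if free_nest_sites > 0 and rng_nest.random() < params.p_nest_daily:
            queen.set_state("founding")
            return "founded"
        return "none"
    return "none"


# ---------------------------------------------------------------------------
# Bee-species CSV interface
# ---------------------------------------------------------------------------

DEFAULT_BEE = BeeSpecies()


def read_bee_table(path: str | _Path) -> list[BeeSpecies]:
    df = pd.read_csv(path)
    missing = [c for c in BEE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bee table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in BEE_COLUMNS]
    if extra:
        warnings.warn(f"bee table: ignoring unknown column(s) {extra}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(BeeSpecies(
                name=str(row["name"]),
                glossa_min_mm=float(row["glossa_min_mm"]),
                glossa_max_mm=float(row["glossa_max_mm"]),
                weight_g=float(row["weight_g"]),
                crop_capacity_ul=float(row["crop_capacity_ul"]),
                emergence_start_doy=int(row["emergence_start_doy"]),
                emergence_end_doy=int(row["emergence_end_doy"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bee table line {i + 2}: {exc}") from exc
    return out


def write_bee_table(bees: list[BeeSpecies], path: str | _Path) -> None:
    pd.DataFrame([
        {
            "name": b.name,
            "glossa_min_mm": b.glossa_min_mm,
            "glossa_max_mm": b.glossa_max_mm,
            "weight_g": b.weight_g,
            "crop_capacity_ul": b.crop_capacity_ul,
            "emergence_start_doy": b.emergence_start_doy,
            "emergence_end_doy": b.emergence_end_doy,
        }
        for b in bees
    ]).to_csv(path, index=False)
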