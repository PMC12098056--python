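"""Colony agents: patch choice, trips, daily step, queens and reproduction."""

import numpy as np
import pytest

from bombusim.colony import (
    BeeSpecies,
    Colony,
    ColonyParams,
    Forager,
    Queen,
    colony_daily_step,
    produce_sexuals,
    queen_daily_step,
    read_bee_table,
    select_patch,
    nectar_trip,
    write_bee_table,
)
from bombusim.flora import FlowerSpecies, Landscape, Patch
from bombusim.handling import ForagerTraits, HandlingConfig

BEE = BeeSpecies()
PARAMS = ColonyParams()
TRAITS = ForagerTraits(glossa_mm=9.0)


def two_patch_land(stock0=1000.0, stock1=1000.0, d0=500.0, d1=500.0,
                   pollen0=1.0, pollen1=1.0):
    sp = FlowerSpecies("forb", 1.5, 1.0, 1.0, pollen_per_flower_g=0.002,
                       flowering_start_doy=1, flowering_end_doy=365)
    patches = [
        Patch(0, d0, 0.0, sp, 1000, 1000.0, stock0, 1.0, pollen0, "semi_improved_pasture"),
        Patch(1, d1, 1.0, sp, 1000, 1000.0, stock1, 1.0, pollen1, "semi_improved_pasture"),
    ]
    return Landscape.from_patches(patches, nest_site_capacity=2)


def make_colony(land, workers=1, store=0.0, pollen=0.0, memory_all=True):
    q = Queen(0, TRAITS, 0.0, 0.0, emergence_doy=80, state="founding")
    col = Colony(0, q, 0, 0.0, 0.0, land.n_patches, nectar_store_ul=store,
                 pollen_store_g=pollen)
    col.attach(land)
    if memory_all:
        col.memory[:] = True
    for _ in range(workers):
        col.workers.append(Forager(glossa_mm=9.0))
    return col


class TestSelectPatch:
    def test_prefers_fuller_patch_at_equal_distance(self, fixed900):
        land = two_patch_land(stock0=200.0, stock1=1000.0)
        col = make_colony(land)
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(0))
        assert choice.idx == 1

    def test_tie_breaks_to_lowest_patch_id(self, fixed900):
        land = two_patch_land()
        col = make_colony(land)
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(0))
        assert choice.idx == 0

    def test_empty_landscape_yields_no_trip(self, fixed900):
        land = two_patch_land(stock0=0.0, stock1=0.0)
        col = make_colony(land)
        assert select_patch(col, land, fixed900, TRAITS, PARAMS,
                            np.random.default_rng(0)) is None

    def test_unmemorised_patch_requires_exploration(self, fixed900):
        land = two_patch_land()
        col = make_colony(land, memory_all=False)
        # no memorised candidate: exploration is forced and returns something
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(1))
        assert choice is not None

    def test_give_up_floor_on_dregs(self, fixed900):
        # a nearly-empty far patch is below the minimum intake rate
        land = two_patch_land(stock0=5.0, stock1=0.0, d0=2000.0)
        col = make_colony(land)
        assert select_patch(col, land, fixed900, TRAITS, PARAMS,
                            np.random.default_rng(0)) is None


class TestNectarTrip:
    def test_duration_composes_engine_and_flight(self, fixed900):
        land = two_patch_land()
        col = make_colony(land)
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(0))
        # γ = 1, fixed 900 s handling, 500 m each way at 5 m/s
        assert choice.duration_s == pytest.approx(2 * 500 / 5 + 900)
        rec = nectar_trip(col, TRAITS, choice, 0.0, np.random.default_rng(0),
                          land, PARAMS, day=1, crop_ul=120.0)
        assert rec.duration_s == choice.duration_s
        assert rec.collected == 120.0
        assert not rec.forager_died

    def test_small_stock_clamps_collection(self, fixed900):
        land = two_patch_land(stock0=50.0, stock1=0.0)
        col = make_colony(land)
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(0))
        rec = nectar_trip(col, TRAITS, choice, 0.0, np.random.default_rng(0),
                          land, PARAMS, day=1, crop_ul=120.0)
        assert rec.collected == 50.0
        assert land.nectar_stock[0] == 0.0

    def test_certain_death_withholds_delivery(self, fixed900):
        land = two_patch_land()
        col = make_colony(land)
        choice = select_patch(col, land, fixed900, TRAITS, PARAMS,
                              np.random.default_rng(0))
        rec = nectar_trip(col, TRAITS, choice, 1e9, np.random.default_rng(0),
                          land, PARAMS, day=1, crop_ul=120.0)
        assert rec.forager_died
        assert col.nectar_store_ul == 0.0
        # the load was still removed from the patch (lost en route)
        assert land.nectar_stock[0] == 1000.0 - 120.0


class TestColonyDailyStep:
    def run_day(self, col, land, doy=150, mort=0.0, engine=None):
        engine = engine or HandlingConfig(fixed_handling_enabled=True,
                                          fixed_handling_time_s=900.0)
        rng = np.random.default_rng(0)
        return colony_daily_step(
            col, land, day=doy, doy=doy, engine_cfg=engine, bee=BEE,
            mort_rate=mort, params=PARAMS, rng_mort=np.random.default_rng(1),
            rng_explore=np.random.default_rng(2),
            rng_traits=np.random.default_rng(3),
        )

    def test_budget_bounds_trip_time(self):
        land = two_patch_land()
        land.nectar_capacity[:] = 1e9  # deep patches stay full (γ ≈ 1)
        land.nectar_stock[:] = 1e9
        col = make_colony(land, workers=1)
        col.brood_ages = [0] * 200  # large deficit keeps the forager busy
        col.pollen_store_g = 10.0
        trips, _ = self.run_day(col, land)
        total = sum(t.duration_s for t in trips)
        assert total <= PARAMS.daily_budget_s
        assert total > PARAMS.daily_budget_s - 1100  # budget nearly used

    def test_satisfied_stores_mean_no_trips(self):
        land = two_patch_land()
        col = make_colony(land, workers=2, store=1e6, pollen=10.0)
        trips, _ = self.run_day(col, land)
        assert trips == []

    def test_dead_colony_is_inert(self):
        land = two_patch_land()
        col = make_colony(land)
        col.alive = False
        trips, n = self.run_day(col, land)
        assert trips == [] and n == 0

    def test_starvation_kills_after_consecutive_empty_days(self):
        land = two_patch_land(stock0=0.0, stock1=0.0)
        col = make_colony(land, workers=3, store=0.0)
        self.run_day(col, land)
        assert col.alive and col.starve_streak == 1
        self.run_day(col, land)
        assert not col.alive
        assert col.queen.state == "dead"


class TestProduceSexuals:
    def make(self, workers, store):
        land = two_patch_land()
        return make_colony(land, workers=workers, store=store)

    def test_no_surplus_no_queens(self):
        col = self.make(workers=10, store=0.0)
        assert produce_sexuals(col, 200, PARAMS) == 0

    def test_floor_of_surplus_over_cost(self):
        col = self.make(workers=10, store=0.0)
        reserve = PARAMS.reserve_days * (
            10 * PARAMS.adult_nectar_ul_day + PARAMS.queen_nectar_ul_day
        )
        col.nectar_store_ul = reserve + 3 * PARAMS.cost_per_queen_ul + 1
        assert produce_sexuals(col, 200, PARAMS) == 3
        assert col.queens_produced == 3

    def test_bounded_by_worker_population(self):
        col = self.make(workers=2, store=0.0)
        reserve = PARAMS.reserve_days * (
            2 * PARAMS.adult_nectar_ul_day + PARAMS.queen_nectar_ul_day
        )
        col.nectar_store_ul = reserve + 10 * PARAMS.cost_per_queen_ul
        assert produce_sexuals(col, 200, PARAMS) == 2

    def test_nothing_before_switch_day(self):
        col = self.make(workers=10, store=1e6)
        assert produce_sexuals(col, PARAMS.switch_doy - 1, PARAMS) == 0


class TestQueenDailyStep:
    def make_queen(self, state="hibernating"):
        return Queen(0, TRAITS, 0, 0, emergence_doy=80, state=state)

    def test_sleeps_before_emergence_day(self):
        q = self.make_queen()
        assert queen_daily_step(q, 79, 5, PARAMS, np.random.default_rng(0)) == "none"
        assert q.state == "hibernating"

    def test_certain_founding_with_free_site(self):
        q = self.make_queen(state="searching")
        params = ColonyParams(p_nest_daily=1.0)
        assert queen_daily_step(q, 100, 1, params, np.random.default_rng(0)) == "founded"

    def test_nest_cap_blocks_founding(self):
        q = self.make_queen(state="searching")
        params = ColonyParams(p_nest_daily=1.0)
        assert queen_daily_step(q, 100, 0, params, np.random.default_rng(0)) == "none"
        assert q.state == "searching"

    def test_no_resurrection(self):
        q = self.make_queen(state="searching")
        q.state = "dead"
        with pytest.raises(ValueError):
            q.set_state("searching")


def test_bee_table_round_trip(tmp_path):
    path = tmp_path / "bees.csv"
    write_bee_table([BEE], path)
    assert read_bee_table(path) == [BEE]
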