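import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import propagule as pg
from propagule import environment as env, ibm


def make_state(day=1):
    return ibm.SimState(day=day)


def flat_rainfall(n_days, wet=False):
    """Deterministic dry (or all-wet) series for controlled stepping."""
    season = np.full(n_days, "wet" if wet else "dry")
    return env.RainfallSeries(rain_mm=np.zeros(n_days), season=season)


class TestIntroduce:
    def test_exact_count_at_entry_cell(self, packed_land, params):
        state = make_state()
        cell = packed_land.entry_points["site1"]
        ibm.introduce(state, 10, cell, packed_land, params,
                      np.random.default_rng(0))
        assert len(state.toads) == 10
        assert np.all(state.toads.cell == cell)
        assert np.all(state.toads.stage == ibm.STAGE_ADULT)
        assert state.flows["introduced"] == 10

    def test_sex_ratio_and_svl_distribution(self, packed_land, params):
        state = make_state()
        cell = packed_land.entry_points["site1"]
        ibm.introduce(state, 10_000, cell, packed_land, params,
                      np.random.default_rng(1))
        svl = state.toads.svl_mm
        male_frac = (state.toads.sex == ibm.SEX_MALE).mean()
        assert abs(male_frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)
        assert abs(svl.mean() - 90.0) < 3 * svl.std(ddof=1) / np.sqrt(10_000)
        assert svl.min() >= 70.0 and svl.max() <= 110.0

    def test_entry_on_water_rejected(self, packed_land, params):
        water_cell = int(np.flatnonzero(packed_land.is_water)[0])
        with pytest.raises(ValueError, match="terrestrial"):
            ibm.introduce(make_state(), 5, water_cell, packed_land, params,
                          np.random.default_rng(0))

    def test_zero_introduction_rejected(self, packed_land, params):
        with pytest.raises(ValueError):
            ibm.introduce(make_state(), 0, packed_land.entry_points["site1"],
                          packed_land, params, np.random.default_rng(0))


class TestHydricState:
    @given(st.floats(min_value=0, max_value=0.09))
    def test_below_first_threshold_hydrated(self, loss):
        assert ibm.hydric_state(loss, ibm.IbmParams()) == ibm.HYD_HYDRATED

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=50))
    def test_monotone_in_loss_fraction(self, losses):
        p = ibm.IbmParams()
        order = np.sort(np.asarray(losses))
        states = ibm.hydric_state(order, p)
        assert np.all(np.diff(states) >= 0)

    def test_thresholds(self):
        p = ibm.IbmParams()
        states = ibm.hydric_state([0.0, 0.10, 0.25, 0.40], p)
        assert list(states) == [ibm.HYD_HYDRATED, ibm.HYD_DEHYDRATED,
                                ibm.HYD_EXTREME, ibm.HYD_DESICCATED]


class TestClutchSize:
    def test_endpoints_of_linear_map(self, params):
        assert ibm.clutch_size(params.adult_svl_mm, params) == 7675
        assert ibm.clutch_size(params.intro_svl_max, params) == 14288

    def test_always_within_fecundity_range(self, params):
        sizes = ibm.clutch_size(np.linspace(50, 150, 200), params)
        assert sizes.min() >= 7675 and sizes.max() <= 14288


class TestBehaviour:
    def _pop(self, packed_land, params, n, stage, sex=ibm.SEX_FEMALE,
             spawned=False, loss=0.0):
        state = make_state()
        cell = packed_land.entry_points["site1"]
        ibm.introduce(state, n, cell, packed_land, params,
                      np.random.default_rng(0))
        state.toads.stage[:] = stage
        state.toads.sex[:] = sex
        state.toads.has_spawned[:] = spawned
        state.toads.hydration_loss[:] = loss
        return state.toads

    def test_juveniles_never_breed_in_wet_season(self, packed_land, params):
        pop = self._pop(packed_land, params, 500, ibm.STAGE_JUVENILE)
        act = ibm.decide_behaviour(pop, packed_land, wet=True, raining=True,
                                   params=params, rng=np.random.default_rng(1))
        assert not np.any(act == ibm.ACT_BREEDING)

    def test_spawned_female_excluded_until_season_reset(self, packed_land, params):
        pop = self._pop(packed_land, params, 500, ibm.STAGE_ADULT, spawned=True)
        act = ibm.decide_behaviour(pop, packed_land, wet=True, raining=True,
                                   params=params, rng=np.random.default_rng(1))
        assert not np.any(act == ibm.ACT_BREEDING)

    def test_dehydrated_toad_rehydrates_in_dry_season(self, packed_land, params):
        pop = self._pop(packed_land, params, 100, ibm.STAGE_ADULT, loss=0.15)
        act = ibm.decide_behaviour(pop, packed_land, wet=False, raining=False,
                                   params=params, rng=np.random.default_rng(1))
        assert np.all(act == ibm.ACT_REHYDRATING)

    def test_active_non_breeders_forage(self, packed_land, params):
        pop = self._pop(packed_land, params, 2000, ibm.STAGE_JUVENILE)
        act = ibm.decide_behaviour(pop, packed_land, wet=True, raining=True,
                                   params=params, rng=np.random.default_rng(1))
        assert set(np.unique(act)) <= {ibm.ACT_INACTIVE, ibm.ACT_FORAGING}
        assert np.any(act == ibm.ACT_FORAGING)


class TestDisperse:
    def test_daily_displacement_never_exceeds_ceiling(self, packed_land, params):
        state = make_state()
        cell = packed_land.entry_points["site1"]
        rng = np.random.default_rng(3)
        ibm.introduce(state, 10_000, cell, packed_land, params, rng)
        pop = state.toads
        pop.activity[:] = ibm.ACT_FORAGING
        x0, y0 = packed_land.grid.centres(pop.cell)
        ibm.disperse(pop, np.ones(len(pop), bool), packed_land, wet=True,
                     params=params, rng=rng)
        x1, y1 = packed_land.grid.centres(pop.cell)
        assert np.hypot(x1 - x0, y1 - y0).max() <= 1000.0

    def test_zero_kernel_scale_stays_in_place(self, packed_land):
        p = ibm.IbmParams(wet_move_scale_m=0.0, dry_move_scale_m=0.0)
        state = make_state()
        cell = packed_land.entry_points["site1"]
        rng = np.random.default_rng(4)
        ibm.introduce(state, 50, cell, packed_land, p, rng)
        pop = state.toads
        pop.activity[:] = ibm.ACT_FORAGING
        before = pop.cell.copy()
        ibm.disperse(pop, np.ones(len(pop), bool), packed_land, wet=False,
                     params=p, rng=rng)
        assert np.array_equal(pop.cell, before)

    def test_rehydrating_moves_toward_water_bfs_oracle(self, packed_land, params):
        # hex breadth-first-search distance from water as independent oracle
        grid = packed_land.grid
        nb = grid.neighbour_matrix()
        dist = np.full(grid.n_cells, -1, dtype=int)
        frontier = np.flatnonzero(packed_land.is_water)
        dist[frontier] = 0
        d = 0
        while frontier.size:
            cand = nb[frontier].ravel()
            cand = np.unique(cand[cand >= 0])
            cand = cand[dist[cand] == -1]
            dist[cand] = d + 1
            frontier = cand
            d += 1
        state = make_state()
        far = int(np.argmax(np.where(packed_land.is_terrestrial, dist, -1)))
        rng = np.random.default_rng(5)
        ibm.introduce(state, 500, far, packed_land, params, rng)
        pop = state.toads
        pop.activity[:] = ibm.ACT_REHYDRATING
        before = dist[pop.cell].mean()
        ibm.disperse(pop, np.ones(len(pop), bool), packed_land, wet=False,
                     params=params, rng=rng)
        after = dist[pop.cell].mean()
        assert after <= before


class TestSpawn:
    def _breeding_state(self, packed_land, params, n=2):
        state = make_state()
        # place a pair on a breeding margin so water is perceptible
        margin = int(np.flatnonzero(packed_land.is_breeding_margin)[0])
        ibm.introduce(state, n, margin, packed_land, params,
                      np.random.default_rng(6))
        state.toads.sex[:] = ibm.SEX_MALE
        state.toads.sex[0] = ibm.SEX_FEMALE
        state.toads.activity[:] = ibm.ACT_BREEDING
        return state

    def test_clutch_size_in_printed_range(self, packed_land, params):
        state = self._breeding_state(packed_land, params)
        cell = ibm.spawn_clutch(state, 0, packed_land, params,
                                np.random.default_rng(7))
        assert cell is not None and packed_land.is_water[cell]
        assert 7675 <= state.clutches.n_eggs[0] <= 14288
        assert state.toads.has_spawned[0]

    def test_pond_with_fewer_tadpoles_chosen(self, packed_land, params):
        state = self._breeding_state(packed_land, params)
        fx, fy = packed_land.grid.centres(int(state.toads.cell[0]))
        ponds = packed_land.water_cells_within(float(fx), float(fy),
                                               params.perception_range_m)
        assert len(ponds) >= 2
        # load every pond except one with many tadpoles
        for p in ponds[:-1]:
            state.clutches.add(cell=int(p), n_eggs=0, n_tadpoles=500,
                               age_days=10, meta_age=40, mother_id=-1)
        chosen = ibm.spawn_clutch(state, 0, packed_land, params,
                                  np.random.default_rng(8))
        assert chosen == int(ponds[-1])

    def test_no_water_within_perception_fails(self, packed_land, params):
        state = make_state()
        _, dist = packed_land.nearest_map("water")
        far = int(np.argmax(np.where(packed_land.is_terrestrial, dist, -np.inf)))
        assert dist[far] > params.perception_range_m
        ibm.introduce(state, 1, far, packed_land, params,
                      np.random.default_rng(9))
        state.toads.sex[0] = ibm.SEX_FEMALE
        state.toads.activity[0] = ibm.ACT_BREEDING
        assert ibm.spawn_clutch(state, 0, packed_land, params,
                                np.random.default_rng(9)) is None


class TestMortality:
    def test_certain_mortality_empties_population(self, packed_land):
        p = ibm.IbmParams(mort_egg=1.0, mort_tadpole=1.0, mort_metamorph=1.0,
                          mort_juvenile=1.0, mort_adult=1.0)
        state = make_state()
        ibm.introduce(state, 100, packed_land.entry_points["site1"],
                      packed_land, p, np.random.default_rng(0))
        state.clutches.add(cell=int(np.flatnonzero(packed_land.is_water)[0]),
                           n_eggs=1000, n_tadpoles=500, age_days=1,
                           meta_age=40, mother_id=-1)
        ibm.apply_mortality(state, packed_land, p, np.random.default_rng(1))
        assert len(state.toads) == 0
        assert len(state.clutches) == 0

    def test_death_count_matches_binomial(self, packed_land, params):
        state = make_state()
        ibm.introduce(state, 10_000, packed_land.entry_points["site1"],
                      packed_land, params, np.random.default_rng(2))
        state.toads.stage[:] = ibm.STAGE_METAMORPH  # p = 0.01
        ibm.apply_mortality(state, packed_land, params, np.random.default_rng(3))
        deaths = 10_000 - len(state.toads)
        p = params.mort_metamorph
        se = np.sqrt(10_000 * p * (1 - p))
        assert abs(deaths - 10_000 * p) < 3 * se

    def test_tadpoles_suppress_cohabiting_eggs(self, packed_land, params):
        water = np.flatnonzero(packed_land.is_water)
        survived = []
        for with_tadpoles in (False, True):
            state = make_state()
            state.clutches.add(cell=int(water[0]), n_eggs=10_000, n_tadpoles=0,
                               age_days=1, meta_age=40, mother_id=-1)
            if with_tadpoles:
                state.clutches.add(cell=int(water[0]), n_eggs=0,
                                   n_tadpoles=200, age_days=10, meta_age=40,
                                   mother_id=-2)
            ibm.apply_mortality(state, packed_land, params,
                                np.random.default_rng(42))
            survived.append(int(state.clutches.n_eggs.sum()))
        assert survived[1] < survived[0]

    def test_desiccated_toads_removed(self, packed_land, params):
        state = make_state()
        ibm.introduce(state, 100, packed_land.entry_points["site1"],
                      packed_land, params, np.random.default_rng(4))
        state.toads.hydration_loss[:50] = 0.45
        p = ibm.IbmParams(mort_metamorph=0, mort_juvenile=0, mort_adult=0)
        ibm.apply_mortality(state, packed_land, p, np.random.default_rng(5))
        assert len(state.toads) == 50


class TestStep:
    def test_clutch_hatches_at_three_days(self, packed_land, params):
        state = make_state()
        water = int(np.flatnonzero(packed_land.is_water)[0])
        state.clutches.add(cell=water, n_eggs=400, n_tadpoles=0, age_days=3,
                           meta_age=40, mother_id=-1)
        state._last_counts = state.compartment_counts()
        p = ibm.IbmParams(mort_egg=0, mort_tadpole=0)
        ibm.step(state, packed_land, flat_rainfall(10), p,
                 np.random.default_rng(0))
        assert state.clutches.n_eggs.sum() == 0
        assert state.clutches.n_tadpoles.sum() == 400

    def test_metamorphosis_creates_terrestrial_toads(self, packed_land, params):
        state = make_state()
        water = int(np.flatnonzero(packed_land.is_water)[0])
        state.clutches.add(cell=water, n_eggs=0, n_tadpoles=300, age_days=40,
                           meta_age=40, mother_id=-1)
        state._last_counts = state.compartment_counts()
        p = ibm.IbmParams(mort_tadpole=0, mort_metamorph=0)
        ibm.step(state, packed_land, flat_rainfall(10), p,
                 np.random.default_rng(0))
        assert len(state.clutches) == 0
        assert len(state.toads) == 300
        assert np.all(state.toads.stage == ibm.STAGE_METAMORPH)
        assert np.all(packed_land.is_terrestrial[state.toads.cell])

    def test_conservation_fixed_point(self, packed_land):
        # no mortality, no water loss, dry season (no spawning): composition
        # is invariant under the daily step
        p = ibm.IbmParams(mort_egg=0, mort_tadpole=0, mort_metamorph=0,
                          mort_juvenile=0, mort_adult=0,
                          daily_water_loss_frac=0.0)
        state = make_state()
        state.validate_ledger = True
        ibm.introduce(state, 50, packed_land.entry_points["site1"],
                      packed_land, p, np.random.default_rng(1))
        before = state.compartment_counts()
        for _ in range(5):
            ibm.step(state, packed_land, flat_rainfall(10), p,
                     np.random.default_rng(2))
        assert np.array_equal(state.compartment_counts(), before)

    def test_replayability_bit_identical(self, packed_land, params, rainfall_3y):
        def run():
            state = make_state(day=295)
            rng = np.random.default_rng(77)
            ibm.introduce(state, 20, packed_land.entry_points["site1"],
                          packed_land, params, rng)
            for _ in range(120):
                ibm.step(state, packed_land, rainfall_3y, params, rng)
            return state
        a, b = run(), run()
        assert np.array_equal(a.toads.id, b.toads.id)
        assert np.array_equal(a.toads.cell, b.toads.cell)
        assert np.array_equal(a.toads.svl_mm, b.toads.svl_mm)
        assert np.array_equal(a.clutches.n_tadpoles, b.clutches.n_tadpoles)
        assert a.tallies == b.tallies

    def test_empty_population_is_fixed_point(self, packed_land, params):
        state = make_state()
        ibm.step(state, packed_land, flat_rainfall(10), params,
                 np.random.default_rng(0))
        assert len(state.toads) == 0 and state.day == 2


class TestGrowthCalibration:
    def test_mean_maturation_age_near_243_days(self, params):
        # iterate the growth update over >= 500 recruits until the adult
        # SVL threshold is crossed
        rng = np.random.default_rng(10)
        n = 1000
        k = params.growth_k * rng.lognormal(0.0, params.growth_k_cv, n)
        svl = np.full(n, params.metamorph_svl_mm)
        age = np.zeros(n, dtype=int)
        for day in range(1, 1500):
            svl = svl + k * (params.svl_asymptote_mm - svl)
            newly = (svl >= params.adult_svl_mm) & (age == 0)
            age[newly] = day
            if np.all(age > 0):
                break
        assert np.all(age > 0)
        assert abs(age.mean() - 243) / 243 < 0.15
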