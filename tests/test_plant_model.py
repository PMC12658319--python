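"""Daily physiological operators: stress, carbon, water, growth, tillers."""

import math

import numpy as np
import pytest

import sorgsim as ss
from sorgsim.phenology import Stage
from sorgsim.plant import (Culm, PhysiologyParams, PlantState, StressState,
                           allocate_growth, compute_stress,
                           daily_photosynthesis, initial_plant_state,
                           maintenance_cost, radiation_interception,
                           tiller_update, transpiration_demand,
                           water_balance_step)

PHYS = PhysiologyParams.from_genotype(ss.default_genotype())
UNSTRESSED = StressState()


def _plant(leaf=20.0, stem=50.0, root=15.0, xylem=100.0):
    main = Culm(leaf_w=leaf, stem_w=stem,
                stem_h=stem / PHYS.stem_density_ref,
                root_w=root, root_l=root / PHYS.root_density_ref)
    return PlantState(main=main, xylem_water=xylem)


class TestComputeStress:
    def test_unstressed_interior(self):
        s = compute_stress(PHYS.cold_opt + 1, PHYS.heat_opt - 1, 20.0, 0.0,
                           PHYS)
        assert (s.air_heat, s.air_cold, s.root, s.water) == (1, 1, 1, 1)

    def test_kill_boundaries(self):
        assert compute_stress(15, PHYS.heat_kill + 1, 20, 0, PHYS).air_heat == 0
        assert compute_stress(PHYS.cold_kill - 1, 25, 20, 0, PHYS).air_cold == 0

    def test_midpoint_is_half(self):
        mid = 0.5 * (PHYS.heat_opt + PHYS.heat_kill)
        s = compute_stress(15, mid, 20, 0, PHYS)
        assert s.air_heat == pytest.approx(0.5, rel=1e-12)

    def test_factors_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = compute_stress(rng.uniform(-30, 50), rng.uniform(-30, 60),
                               rng.uniform(-20, 50), rng.uniform(0, 1), PHYS)
            for v in (s.air_heat, s.air_cold, s.root, s.water):
                assert 0.0 <= v <= 1.0


class TestRadiationInterception:
    def test_no_leaves_no_interception(self):
        assert radiation_interception(0.0, 14.56, 20.0, PHYS) == 0.0

    def test_full_closure_asymptote(self):
        per_plant = radiation_interception(1e7, 14.56, 20.0, PHYS)
        assert per_plant * 14.56 == pytest.approx(20.0, rel=1e-9)

    def test_doubling_density_reduces_per_plant_share(self):
        for leaf in (5.0, 20.0, 80.0):
            low = radiation_interception(leaf, 10.0, 20.0, PHYS)
            high = radiation_interception(leaf, 20.0, 20.0, PHYS)
            assert high < low

    def test_matches_beer_law_oracle(self):
        leaf, stand, rad = 30.0, 14.56, 22.0
        lai = PHYS.sla * leaf * stand
        expected = rad * (1 - math.exp(-PHYS.k_light * lai)) / stand
        assert radiation_interception(leaf, stand, rad, PHYS) == \
            pytest.approx(expected, rel=1e-12)

    def test_zero_stand_rejected(self):
        with pytest.raises(ValueError):
            radiation_interception(10.0, 0.0, 20.0, PHYS)


class TestDailyPhotosynthesis:
    def test_dark_day_yields_nothing(self):
        assert daily_photosynthesis(_plant(), 0.0, UNSTRESSED, 1e4, PHYS) == 0.0

    def test_no_leaves_yields_nothing(self):
        assert daily_photosynthesis(_plant(leaf=0.0), 5.0, UNSTRESSED, 1e4,
                                    PHYS) == 0.0

    def test_minimum_of_caps_binds(self):
        # enumerate each cap as the binding one and compare to the oracle
        plant = _plant(leaf=30.0)
        cases = [
            dict(intercepted=0.1, water=1e6),                  # light binds
            dict(intercepted=100.0, water=50.0),               # water binds
            dict(intercepted=100.0, water=1e6, leaf=1.0),      # leaf binds
            dict(intercepted=100.0, water=1e6, leaf=500.0),    # phloem binds
        ]
        for case in cases:
            p = _plant(leaf=case.get("leaf", 30.0))
            got = daily_photosynthesis(p, case["intercepted"], UNSTRESSED,
                                       case["water"], PHYS)
            expected = min(PHYS.rue * case["intercepted"],
                           PHYS.water_cap_coeff * case["water"],
                           PHYS.leaf_cap_coeff * p.leaf_weight,
                           PHYS.phloem_cap)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_heat_cold_stress_scales_output(self):
        stress = StressState(air_heat=0.4, air_cold=0.9)
        full = daily_photosynthesis(_plant(), 100.0, UNSTRESSED, 1e6, PHYS)
        assert daily_photosynthesis(_plant(), 100.0, stress, 1e6, PHYS) == \
            pytest.approx(0.4 * full, rel=1e-12)


class TestTranspirationDemand:
    def test_saturated_air_no_demand(self):
        assert transpiration_demand(25.0, 100.0, 3.0, 5.0, 30.0, PHYS) == 0.0

    def test_no_leaves_no_demand(self):
        assert transpiration_demand(25.0, 50.0, 3.0, 5.0, 0.0, PHYS) == 0.0

    def test_monotone_in_wind_and_dryness(self):
        base = transpiration_demand(25.0, 60.0, 2.0, 5.0, 30.0, PHYS)
        assert transpiration_demand(25.0, 60.0, 5.0, 5.0, 30.0, PHYS) > base
        assert transpiration_demand(25.0, 40.0, 2.0, 5.0, 30.0, PHYS) > base
        assert transpiration_demand(25.0, 80.0, 2.0, 5.0, 30.0, PHYS) < base


class TestWaterBalance:
    def test_no_roots_full_deficit(self):
        plant = _plant(root=0.0, xylem=0.0)
        plant.main.root_l = 0.0
        _, deficit = water_balance_step(plant, 0.3, 100.0, 14.56, PHYS)
        assert deficit == 1.0

    def test_ample_uptake_no_deficit(self):
        plant = _plant(root=100.0, xylem=50.0)
        before = plant.xylem_water
        _, deficit = water_balance_step(plant, 0.4, 10.0, 14.56, PHYS)
        assert deficit == 0.0
        assert plant.xylem_water >= before

    def test_uptake_capped_by_transport(self):
        plant = _plant(root=1e6, xylem=0.0)
        plant.main.root_l = 1e6
        water_balance_step(plant, 1.0, 0.0, 1.0, PHYS)
        assert plant.diag["uptake"] == pytest.approx(PHYS.xylem_transport_cap)

    def test_xylem_bounded_by_capacity(self):
        plant = _plant(root=500.0, xylem=PHYS.xylem_capacity)
        water_balance_step(plant, 0.4, 0.0, 1.0, PHYS)
        assert plant.xylem_water <= PHYS.xylem_capacity

    def test_deficit_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            plant = _plant(root=rng.uniform(0, 50),
                           xylem=rng.uniform(0, PHYS.xylem_capacity))
            plant.main.root_l = plant.main.root_w / PHYS.root_density_ref
            _, d = water_balance_step(plant, rng.uniform(0, 1),
                                      rng.uniform(0, 2000),
                                      rng.uniform(1, 40), PHYS)
            assert 0.0 <= d <= 1.0


class TestMaintenance:
    def test_zero_weights_zero_cost(self):
        plant = PlantState(main=Culm())
        cost, sen = maintenance_cost(plant, UNSTRESSED, PHYS)
        assert cost == 0.0
        assert all(v == 0.0 for d in sen for v in d.values())

    def test_unstressed_plant_has_no_senescence(self):
        cost, sen = maintenance_cost(_plant(), UNSTRESSED, PHYS)
        assert cost > 0.0
        assert all(v == 0.0 for d in sen for v in d.values())

    def test_cost_linear_in_weights(self):
        p1 = _plant(leaf=10, stem=20, root=5)
        p2 = _plant(leaf=20, stem=40, root=10)
        c1, _ = maintenance_cost(p1, UNSTRESSED, PHYS)
        c2, _ = maintenance_cost(p2, UNSTRESSED, PHYS)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_tiller_organs_included(self):
        plant = _plant()
        cost_before, _ = maintenance_cost(plant, UNSTRESSED, PHYS)
        plant.tillers.append(Culm(leaf_w=5.0, root_w=2.0, root_l=4.0))
        cost_after, sen = maintenance_cost(plant, UNSTRESSED, PHYS)
        assert cost_after == pytest.approx(
            cost_before + 5.0 * PHYS.maint_leaf + 2.0 * PHYS.maint_root)
        assert len(sen) == 2

    def test_stressed_senescence_proportional_to_stress_gap(self):
        stress = StressState(air_cold=0.4)
        _, sen = maintenance_cost(_plant(leaf=10.0), stress, PHYS)
        assert sen[0]["leaf"] == pytest.approx(
            PHYS.senescence_leaf * 0.6 * 10.0, rel=1e-12)


def _no_sen(state):
    return [{} for _ in state.culms()]


class TestAllocateGrowth:
    def test_zero_net_identity(self):
        plant = _plant()
        before = (plant.main.leaf_w, plant.main.stem_w, plant.main.root_w,
                  plant.main.stem_h, plant.main.root_l)
        allocate_growth(plant, 5.0, 5.0, _no_sen(plant), Stage.VEGETATIVE,
                        UNSTRESSED, PHYS)
        after = (plant.main.leaf_w, plant.main.stem_w, plant.main.root_w,
                 plant.main.stem_h, plant.main.root_l)
        assert after == before

    def test_deficit_remobilizes_weight_not_dimensions(self):
        plant = _plant()
        h, l = plant.main.stem_h, plant.main.root_l
        total = plant.total_weight()
        allocate_growth(plant, 0.0, 4.0, _no_sen(plant), Stage.VEGETATIVE,
                        UNSTRESSED, PHYS)
        assert plant.main.stem_h == h
        assert plant.main.root_l == l
        assert plant.total_weight() == pytest.approx(total - 4.0, rel=1e-12)

    def test_remobilization_order_stem_root_leaf(self):
        plant = _plant(leaf=10.0, stem=3.0, root=2.0)
        allocate_growth(plant, 0.0, 4.0, _no_sen(plant), Stage.VEGETATIVE,
                        UNSTRESSED, PHYS)
        assert plant.main.stem_w == pytest.approx(0.0, abs=1e-12)
        assert plant.main.root_w == pytest.approx(1.0, rel=1e-9)
        assert plant.main.leaf_w == pytest.approx(10.0)

    def test_density_restored_before_new_growth(self):
        # deficit day then a larger surplus day, stepped by hand
        plant = _plant(leaf=10.0, stem=24.0, root=6.0)
        h0, l0 = plant.main.stem_h, plant.main.root_l
        allocate_growth(plant, 0.0, 6.0, _no_sen(plant), Stage.VEGETATIVE,
                        UNSTRESSED, PHYS)
        stem_gap = PHYS.stem_density_ref * h0 - plant.main.stem_w
        root_gap = PHYS.root_density_ref * l0 - plant.main.root_w
        assert stem_gap + root_gap == pytest.approx(6.0, rel=1e-9)
        # surplus worth more structure than the 6 g gap
        surplus = 6.0 / PHYS.growth_efficiency + 10.0
        allocate_growth(plant, surplus, 0.0, _no_sen(plant),
                        Stage.VEGETATIVE, UNSTRESSED, PHYS)
        # densities fully restored...
        assert plant.main.stem_w >= PHYS.stem_density_ref * h0 - 1e-9
        assert plant.main.root_w >= PHYS.root_density_ref * l0 - 1e-9
        # ...and only the remainder grew dimensions
        frac = PHYS.partitions[Stage.VEGETATIVE]
        expected_h = h0 + 10.0 * PHYS.growth_efficiency * frac[1] / PHYS.stem_density_ref
        assert plant.main.stem_h == pytest.approx(expected_h, rel=1e-9)

    def test_carbon_closure_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            plant = _plant(leaf=rng.uniform(0, 40), stem=rng.uniform(0, 120),
                           root=rng.uniform(0, 40))
            stress = StressState(air_cold=rng.uniform(0.2, 1.0))
            _, sen = maintenance_cost(plant, stress, PHYS)
            assim, maint = rng.uniform(0, 12), rng.uniform(0, 12)
            before = plant.total_weight()
            allocate_growth(plant, assim, maint, sen, Stage.VEGETATIVE,
                            stress, PHYS)
            d = plant.diag
            expected = (d["structural_gain"] - d["remobilized"]
                        - d["senesced"])
            change = plant.total_weight() - before
            assert change == pytest.approx(expected,
                                           abs=1e-9 * max(1.0, before))
            net = assim - maint
            if net >= 0:
                assert d["structural_gain"] == pytest.approx(
                    net * PHYS.growth_efficiency, rel=1e-12)
            elif not d["remobilization_floored"]:
                assert d["remobilized"] == pytest.approx(-net, rel=1e-12)

    def test_senescence_floors_at_zero(self):
        plant = _plant(leaf=0.5)
        sen = [{"leaf": 10.0}]
        allocate_growth(plant, 0.0, 0.0, sen, Stage.VEGETATIVE, UNSTRESSED,
                        PHYS)
        assert plant.main.leaf_w == 0.0


class TestTillerUpdate:
    def test_disabled_when_tiller_max_zero(self):
        g = ss.default_genotype().replace(tiller_max=0.0)
        phys = PhysiologyParams.from_genotype(g)
        plant = _plant()
        plant.reserve_carbon = 100.0
        tiller_update(plant, Stage.VEGETATIVE, phys, cumulative_gdu=1e5)
        assert plant.tillers == []

    def test_no_tiller_below_trigger(self):
        plant = _plant()
        plant.reserve_carbon = PHYS.tiller_trigger - 0.01
        tiller_update(plant, Stage.VEGETATIVE, PHYS, cumulative_gdu=1e5)
        assert plant.tillers == []

    def test_initiation_day_and_mass_conservation(self):
        plant = _plant()
        plant.reserve_carbon = PHYS.tiller_trigger + 1.0
        total = plant.total_weight()
        tiller_update(plant, Stage.VEGETATIVE, PHYS, cumulative_gdu=1e5,
                      day=37)
        assert len(plant.tillers) == 1
        assert plant.tillers[0].initiation_day == 37
        assert plant.total_weight() == pytest.approx(total, rel=1e-12)

    def test_requires_vegetative_stage_and_thermal_time(self):
        plant = _plant()
        plant.reserve_carbon = 100.0
        tiller_update(plant, Stage.PLANTED, PHYS, cumulative_gdu=1e5)
        assert plant.tillers == []
        tiller_update(plant, Stage.VEGETATIVE, PHYS,
                      cumulative_gdu=PHYS.tiller_gdu_min - 1)
        assert plant.tillers == []


class TestInitialState:
    def test_seeded_pools_at_full_density(self):
        state = initial_plant_state(PHYS)
        assert state.main.leaf_w == PHYS.seed_leaf_weight
        assert state.main.stem_w / state.main.stem_h == \
            pytest.approx(PHYS.stem_density_ref, rel=1e-9)
        assert state.xylem_water == pytest.approx(
            PHYS.initial_xylem_fraction * PHYS.xylem_capacity)

    def test_stress_state_validates_range(self):
        with pytest.raises(ValueError):
            StressState(air_heat=1.5)
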