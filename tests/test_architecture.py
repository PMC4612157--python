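"""Canopy construction, organ growth responses and trait scaling."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saltcanopy as sc
from saltcanopy.architecture import _leaf_geometry, g_salinity, g_temperature, g_vpd


def grow(params, treatment, n_days, seed=0, regime=None, climate_seed=1):
    regime = regime or treatment.regime
    climate = sc.generate_climate(n_days, regime=regime, seed=climate_seed)
    canopy = sc.init_canopy(params, seed=seed)
    for day in climate:
        sc.step_day(canopy, day, treatment, params)
    return canopy


class TestCanopyLayout:
    def test_sixteen_plants_on_metre_grid(self):
        canopy = sc.init_canopy(seed=0)
        pos = sorted((p.x, p.y) for p in canopy.plants)
        assert pos == [(float(i), float(j)) for i in range(4) for j in range(4)]

    def test_same_seed_reproduces_canopy(self, params):
        a = grow(params, sc.Treatment("LT", 0.0), 30, seed=5)
        b = grow(params, sc.Treatment("LT", 0.0), 30, seed=5)
        for pa, pb in zip(a.plants, b.plants):
            assert pa.azimuths == pb.azimuths
            assert pa.leaf_len == pb.leaf_len

    def test_zero_jitter_gives_exact_phyllotaxis(self, params):
        p = dataclasses.replace(params, phyllotaxis_jitter_deg=0.0)
        canopy = grow(p, sc.Treatment("LT", 0.0), 40)
        for plant in canopy.plants:
            inc = np.diff(plant.azimuths) % 360.0
            assert np.allclose(inc, 144.0)

    def test_jittered_phyllotaxis_centres_on_144(self, params):
        canopy = grow(params, sc.Treatment("LT", 0.0), 60, seed=3)
        inc = np.concatenate([np.diff(p.azimuths) for p in canopy.plants]) % 360.0
        # circular mean of increments ~ 144 +- jitter/sqrt(n)
        assert abs(np.mean(inc) - 144.0) < 10.0 / math.sqrt(len(inc)) * 4


class TestOrganGrowth:
    def test_salinity_modifier_matches_closed_form(self):
        # g_S = 1 + c_el_max * x * vpd at the reference sensitivity
        assert g_salinity(80.0, 2.0, -0.0006) == pytest.approx(0.904, abs=1e-12)
        assert g_salinity(0.0, 2.0, -0.0006) == 1.0

    def test_zero_salinity_leaf_rate_is_potential_times_environment(self, params):
        day = sc.ClimateDay(dafla=5, t_day=25.0, t_night=25.0, vpd=1.0, par=8.0)
        rate = sc.organ_elongation("leaf", 100.0, day, 0.0, params)
        # at the temperature optimum and 1 kPa both modifiers are 1
        assert g_temperature(25.0) == 1.0 and g_vpd(1.0) == 1.0
        assert rate > 0

    def test_internode_rate_unaffected_by_salinity(self, params):
        day = sc.ClimateDay(dafla=5, t_day=22.0, t_night=18.0, vpd=1.5, par=8.0)
        r0 = sc.organ_elongation("internode", 50.0, day, 0.0, params)
        r80 = sc.organ_elongation("internode", 50.0, day, 80.0, params)
        assert r80 == r0

    def test_negative_salinity_rejected(self, params):
        day = sc.ClimateDay(dafla=1, t_day=22.0, t_night=18.0, vpd=1.0, par=8.0)
        with pytest.raises(ValueError):
            sc.organ_elongation("leaf", 10.0, day, -5.0, params)

    @given(age=st.floats(0, 400), x=st.floats(0, 100), vpd=st.floats(0.2, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_leaf_rate_nonnegative_and_salinity_monotone(self, age, x, vpd):
        params = sc.GrowthParams()
        day = sc.ClimateDay(dafla=1, t_day=24.0, t_night=18.0, vpd=vpd, par=8.0)
        r = sc.organ_elongation("leaf", age, day, x, params)
        r0 = sc.organ_elongation("leaf", age, day, 0.0, params)
        assert r >= 0.0
        assert r <= r0 + 1e-15

    def test_organ_lengths_nondecreasing_and_capped(self, params):
        treatment = sc.Treatment("LT", 0.0)
        climate = sc.generate_climate(77, "LT", seed=1)
        canopy = sc.init_canopy(params, seed=0)
        prev_leaf, prev_area = None, -1.0
        for day in climate:
            sc.step_day(canopy, day, treatment, params)
            plant = canopy.plants[0]
            if prev_leaf is not None:
                for r in range(len(prev_leaf)):
                    assert plant.leaf_len[r] >= prev_leaf[r] - 1e-12
            area = sc.total_leaf_area(canopy)
            assert area >= prev_area
            prev_leaf, prev_area = list(plant.leaf_len), area
        assert max(canopy.plants[0].leaf_len) <= params.l_max + 1e-12

    def test_final_leaf_number_in_calibration_band(self, params):
        canopy = grow(params, sc.Treatment("LT", 0.0), 80)
        n = sc.leaf_number(canopy.plants[0])
        assert 25 <= n <= 35


@pytest.fixture(scope="module")
def canopies(params):
    p = dataclasses.replace(params, phyllotaxis_jitter_deg=0.0)
    return {x: grow(p, sc.Treatment("LT", x), 60) for x in (0.0, 40.0, 80.0)}


class TestSalinityEffects:
    def test_before_application_identical(self, params):
        p = dataclasses.replace(params, phyllotaxis_jitter_deg=0.0)
        a = grow(p, sc.Treatment("LT", 0.0, salinity_start=21), 20)
        b = grow(p, sc.Treatment("LT", 80.0, salinity_start=21), 20)
        for pa, pb in zip(a.plants, b.plants):
            assert pa.leaf_len == pb.leaf_len

    def test_leaf_area_decreases_with_salinity(self, canopies):
        a0 = sc.total_leaf_area(canopies[0.0])
        a40 = sc.total_leaf_area(canopies[40.0])
        a80 = sc.total_leaf_area(canopies[80.0])
        assert a0 > a40 > a80

    def test_internode_lengths_invariant_to_salinity(self, canopies):
        for p0, p80 in zip(canopies[0.0].plants, canopies[80.0].plants):
            assert p0.int_len == p80.int_len
            assert sc.plant_height(p0) == sc.plant_height(p80)


class TestTraitScaling:
    def test_identity_factor_only_changes_target_field(self, params):
        assert sc.apply_trait_scaling(params, "leaf_angle", 1.0) == params

    def test_c_el_max_scaling(self, params):
        half = sc.apply_trait_scaling(params, "c_el_max", 0.5)
        assert half.c_el_max == pytest.approx(-0.0003)

    def test_per_10mm_rate_to_overall_factor(self):
        assert sc.salinity_trait_factor(0.03, 40.0) == pytest.approx(0.88)
        assert sc.salinity_trait_factor(0.06, 80.0) == pytest.approx(0.52)

    def test_leaf_number_factor_scales_final_count(self, params):
        ref = grow(params, sc.Treatment("LT", 40.0), 77)
        scaled = grow(sc.apply_trait_scaling(params, "leaf_number", 0.88),
                      sc.Treatment("LT", 40.0), 77)
        n_ref = sc.leaf_number(ref.plants[0])
        n_scaled = sc.leaf_number(scaled.plants[0])
        assert abs(n_scaled - 0.88 * n_ref) <= 1.0

    def test_unknown_trait_rejected(self, params):
        with pytest.raises(ValueError):
            sc.apply_trait_scaling(params, "root_depth", 0.5)


class TestGeometry:
    def test_leaflet_areas_sum_to_blade_area(self, params):
        L = 37.0
        tris, areas = _leaf_geometry(np.zeros(3), 30.0, L, params)
        blade = params.blade_area_coeff * (L / 100.0) ** 2
        assert areas.sum() == pytest.approx(blade, rel=1e-9)
        assert tris.shape == (14, 3, 3)

    def test_mesh_area_matches_bookkeeping(self, day77_mesh, params, lt_climate):
        canopy = sc.init_canopy(params, seed=0)
        for day in lt_climate:
            sc.step_day(canopy, day, sc.Treatment("LT", 0.0), params)
        reported = sc.total_leaf_area(canopy) * len(canopy.plants) / 1e4  # m2
        mesh_area = day77_mesh.triangle_areas()[~day77_mesh.is_ground].sum()
        assert abs(mesh_area - reported) / reported < 1e-6
        assert (day77_mesh.triangle_areas() > 0).all()

    def test_every_leaflet_contributes_two_triangles(self, day77_mesh):
        leaf_ids, counts = np.unique(
            day77_mesh.surface_id[~day77_mesh.is_ground], return_counts=True)
        assert (counts == 2).all()
        assert len(leaf_ids) == day77_mesh.n_leaf_surfaces

    def test_plant_height_is_internode_sum(self):
        plant = sc.architecture.Plant(x=0, y=0)
        plant.int_len = [2.0, 3.0, 5.0]
        assert sc.plant_height(plant) == 10.0

    def test_empty_canopy_gives_empty_leaf_mesh(self, params):
        canopy = sc.init_canopy(params, seed=0)  # day 0: zero-length leaves
        mesh = sc.to_mesh(canopy, include_ground=False)
        assert mesh.n_triangles == 0
        assert sc.total_leaf_area(canopy) == 0.0
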