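"""Sky dome weights and Monte Carlo light transport against analytic oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

import saltcanopy as sc
from saltcanopy.light import (_diffuse_band_weight, max_solar_elevation,
                              solar_declination)

ADAX_ABS = 1.0 - 0.073 - 0.024  # absorbed fraction, adaxial incidence


def mc_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1 - p), 1e-12) / n)


class TestSkyDome:
    def test_weights_normalised_and_downward(self):
        sky = sc.build_sky(52.38, 9.62, day_of_year=120)
        assert sky.weights.sum() == pytest.approx(1.0)
        assert (sky.directions[:, 2] < 0).all()
        assert np.allclose(np.linalg.norm(sky.directions, axis=1), 1.0)

    @pytest.mark.parametrize("kind", ["uoc", "soc"])
    def test_band_weights_match_numerical_integration(self, kind):
        # independent oracle: quadrature of L(e) sin(e) cos(e)
        def radiance(e):
            return 1.0 if kind == "uoc" else (1.0 + 2.0 * math.sin(e)) / 3.0

        edges = np.linspace(0, math.pi / 2, 7)
        for e1, e2 in zip(edges[:-1], edges[1:]):
            num, _ = integrate.quad(
                lambda e: radiance(e) * math.sin(e) * math.cos(e), e1, e2)
            assert _diffuse_band_weight(e1, e2, kind) == pytest.approx(num, abs=1e-9)

    def test_fully_diffuse_dome_matches_overcast_standard(self):
        sky = sc.build_sky(0.0, day_of_year=80, diffuse_fraction=1.0, kind="soc")
        edges = np.linspace(0, math.pi / 2, 7)
        total = sum(_diffuse_band_weight(a, b, "soc")
                    for a, b in zip(edges[:-1], edges[1:]))
        for a, b in zip(edges[:-1], edges[1:]):
            mask = (-sky.directions[:, 2] >= math.sin(a) - 1e-9) \
                & (-sky.directions[:, 2] <= math.sin(b) + 1e-9)
            got = sky.weights[mask].sum()
            assert got == pytest.approx(_diffuse_band_weight(a, b, "soc") / total,
                                        abs=1e-6)

    def test_equatorial_equinox_beam_peaks_at_zenith(self):
        sky = sc.build_sky(0.0, day_of_year=80, diffuse_fraction=0.0)
        peak = sky.directions[np.argmax(sky.weights)]
        zenith_angle = math.degrees(math.acos(min(1.0, -peak[2])))
        assert zenith_angle < 1.0

    def test_hannover_spring_noon_elevation(self):
        # solar declination oracle: 90 - |lat - dec|
        assert 50.0 <= max_solar_elevation(52.38, 120) <= 55.0
        dec = solar_declination(172)
        assert dec == pytest.approx(23.45, abs=0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.build_sky(95.0, day_of_year=100)
        with pytest.raises(ValueError):
            sc.build_sky(50.0, day_of_year=0)


class TestTracerOracles:
    def test_single_leaflet_absorbs_analytic_fraction(self):
        # horizontal unit leaflet, vertical beam onto the adaxial side
        mesh = sc.simple_scene([(0, 1, 0, 1, 1.0)])
        n = 200_000
        amap = sc.trace(mesh, sc.SkyDome.beam(), n_rays=n, seed=3)
        frac = amap.leaf_absorbed / amap.incident
        assert abs(frac - ADAX_ABS) < 3 * mc_se(ADAX_ABS, n)

    def test_empty_scene_full_transmittance_and_ground_absorption(self):
        mesh = sc.simple_scene([], ground_rect=(0, 4, 0, 4))
        sky = sc.build_sky(52.38, day_of_year=120, diffuse_fraction=0.5)
        amap = sc.trace(mesh, sky, n_rays=50_000, seed=1)
        assert amap.transmittance == pytest.approx(1.0, abs=0.01)
        assert amap.ground_absorbed / amap.incident_ground == pytest.approx(0.2, abs=0.01)

    def test_opaque_sheet_blocks_ground(self):
        optics = sc.OpticalProps(adaxial_transmit=0.0, abaxial_transmit=0.0)
        mesh = sc.simple_scene([(-1, 5, -1, 5, 1.0)], ground_rect=(0, 4, 0, 4))
        amap = sc.trace(mesh, sc.SkyDome.beam(), optics, n_rays=20_000, seed=2,
                        emission_margin=0.0)
        assert amap.transmittance == pytest.approx(0.0, abs=1e-3)

    def test_two_layer_absorption_matches_geometric_series(self):
        # vertical beam on two stacked horizontal layers; multiple
        # reflections between layer-1 abaxial and layer-2 adaxial follow
        # a geometric series with ratio rho_ad * rho_ab
        rho_ad, tau_ad, rho_ab, tau_ab = 0.073, 0.024, 0.127, 0.025
        a_ad, a_ab = 1 - rho_ad - tau_ad, 1 - rho_ab - tau_ab
        r = rho_ad * rho_ab
        f2 = tau_ad / (1 - r)          # total flux onto layer-2 top
        abs2 = f2 * a_ad               # layer 2 absorbs at adaxial rates
        abs1 = a_ad + f2 * rho_ad * a_ab  # direct + returning flux on abaxial
        mesh = sc.simple_scene([(0, 4, 0, 4, 1.0), (0, 4, 0, 4, 0.995)])
        n = 400_000
        amap = sc.trace(mesh, sc.SkyDome.beam(), n_rays=n, seed=5,
                        emission_margin=0.0)
        got1 = amap.per_surface_absorbed[0] / 1e6
        got2 = amap.per_surface_absorbed[1] / 1e6
        assert abs(got1 - abs1) < 3 * mc_se(abs1, n)
        assert abs(got2 - abs2) < 3 * mc_se(abs2, n)

    def test_empty_mesh_sends_everything_to_escape(self):
        amap = sc.trace(sc.simple_scene([]), sc.SkyDome.beam(), n_rays=10, seed=0)
        assert amap.leaf_absorbed == 0.0
        assert math.isnan(amap.transmittance)


class TestTracerProperties:
    def test_energy_budget_closes_exactly(self, day77_mesh):
        sky = sc.build_sky(52.38, day_of_year=150)
        amap = sc.trace(day77_mesh, sky, n_rays=50_000, seed=7, daily_par_mj=8.0)
        assert amap.energy_residual() < 1e-12
        assert 0.0 <= amap.transmittance <= 1.0

    def test_same_seed_reproduces_absorption_map(self, day77_mesh):
        sky = sc.build_sky(52.38, day_of_year=150)
        a = sc.trace(day77_mesh, sky, n_rays=20_000, seed=11)
        b = sc.trace(day77_mesh, sky, n_rays=20_000, seed=11)
        assert np.array_equal(a.per_surface_absorbed, b.per_surface_absorbed)
        assert a.transmittance == b.transmittance

    def test_transmittance_estimates_consistent_across_ray_counts(self, day77_mesh):
        sky = sc.build_sky(52.38, day_of_year=150)
        a = sc.trace(day77_mesh, sky, n_rays=20_000, seed=1)
        b = sc.trace(day77_mesh, sky, n_rays=40_000, seed=2)
        se = mc_se(a.transmittance, 20_000) + mc_se(b.transmittance, 40_000)
        assert abs(a.transmittance - b.transmittance) < 4 * se

    def test_beer_lambert_in_turbid_scene(self):
        # randomly dispersed horizontal leaves: ln(Q_T/Q_0) linear in LAI
        rng = np.random.default_rng(0)
        lais = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        ts = []
        for lai in lais:
            n = int(lai * 16 / 0.04)
            rects = [(x, x + 0.2, y, y + 0.2, z)
                     for x, y, z in zip(rng.uniform(0, 3.8, n),
                                        rng.uniform(0, 3.8, n),
                                        rng.uniform(0.1, 1.9, n))]
            mesh = sc.simple_scene(rects, ground_rect=(0, 4, 0, 4))
            amap = sc.trace(mesh, sc.SkyDome.beam(), n_rays=30_000, seed=1,
                            emission_margin=0.0)
            ts.append(amap.transmittance)
        slope, intercept = np.polyfit(lais, np.log(ts), 1)
        resid = np.log(ts) - (slope * lais + intercept)
        r2 = 1 - resid.var() / np.var(np.log(ts))
        assert slope < 0
        assert r2 > 0.98

    def test_transmittance_requires_incident_flux(self):
        amap = sc.trace(sc.simple_scene([], ground_rect=(0, 1, 0, 1)),
                        sc.SkyDome.beam(), n_rays=100, seed=0)
        amap.incident = 0.0
        with pytest.raises(ValueError):
            sc.canopy_transmittance(amap)
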