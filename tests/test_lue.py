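"""Estimation and multiplicative dissection of relative light-use efficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, seed as hyp_seed, settings, strategies as st

import saltcanopy as sc
from saltcanopy.lue import recompose, round_half_up
from conftest import INTERVALS, REFERENCE_K_FACTORS


class TestEstimateK:
    def test_identical_series_gives_unit_k(self, lt_reference):
        wm = sc.harvest_masses(lt_reference, sc.HARVEST_DAYS)
        ks = sc.estimate_k(wm, lt_reference)
        assert all(k == pytest.approx(1.0) for k in ks.values())

    def test_proportional_increments_give_constant_k(self, lt_reference):
        wm = sc.harvest_masses(lt_reference, sc.HARVEST_DAYS)
        w28 = wm[28]
        scaled = {d: w28 + 0.8 * (w - w28) for d, w in wm.items()}
        ks = sc.estimate_k(scaled, lt_reference)
        assert all(k == pytest.approx(0.8, rel=1e-12) for k in ks.values())

    def test_consistent_mass_rescaling_scales_k(self, lt_reference):
        wm = sc.harvest_masses(lt_reference, sc.HARVEST_DAYS)
        ks = sc.estimate_k({d: 1.7 * w for d, w in wm.items()}, lt_reference)
        assert all(k == pytest.approx(1.7, rel=1e-12) for k in ks.values())

    def test_degenerate_reference_interval_is_named(self, lt_reference):
        flat = lt_reference.copy()
        flat["w_sh"] = 100.0
        wm = sc.harvest_masses(lt_reference, sc.HARVEST_DAYS)
        with pytest.raises(ValueError, match="29-35"):
            sc.estimate_k(wm, flat)

    def test_missing_harvest_day_rejected(self, lt_reference):
        with pytest.raises(ValueError):
            sc.estimate_k({28: 1.0, 35: 2.0}, lt_reference)


class TestEndToEndRecovery:
    def test_zero_noise_recovery_all_modes_that_apply(self, lt_reference):
        rng = np.random.default_rng(11)
        treatment = sc.Treatment("LT", 0.0)
        sched = sc.random_k_schedule(rng)
        gt = sc.GroundTruth(k_schedules={treatment.label: sched},
                            allometry_params={"LT": (0.75, 5.0)}, noise_cv=0.0)
        records = sc.generate_harvests(gt, [treatment],
                                       {treatment.label: lt_reference},
                                       n_reps=2, seed=1)
        fit = sc.fit_allometry(records)[("LT", "nonstress")]
        for mode in ("measured_area", "measured_mass"):
            wm = sc.measured_mass_series(records, fit=fit, mode=mode)
            ks = sc.estimate_k(wm, lt_reference)
            for iv, k_true in sched.intervals.items():
                assert ks[iv] == pytest.approx(k_true, rel=0.02)

    def test_zero_noise_closure_is_tight(self, lt_reference):
        rng = np.random.default_rng(13)
        treatment = sc.Treatment("LT", 0.0)
        sched = sc.random_k_schedule(rng)
        gt = sc.GroundTruth(k_schedules={treatment.label: sched},
                            allometry_params={"LT": (0.75, 5.0)}, noise_cv=0.0)
        records = sc.generate_harvests(gt, [treatment],
                                       {treatment.label: lt_reference},
                                       n_reps=1, seed=2)
        fit = sc.fit_allometry(records)[("LT", "nonstress")]
        wm = sc.measured_mass_series(records, fit=fit)
        ks = sc.estimate_k(wm, lt_reference)
        report = sc.closure_run(ks, lt_reference, wm, fit=fit)
        assert report["max_rel_mass_error"] < 0.02

    def test_unit_k_closure_is_exact(self, lt_reference):
        wm = sc.harvest_masses(lt_reference, sc.HARVEST_DAYS)
        ks = {iv: 1.0 for iv in sc.K_INTERVALS}
        report = sc.closure_run(ks, lt_reference, wm)
        assert report["max_rel_mass_error"] < 1e-12

    def test_noisy_closure_slope_within_fit_ci(self, lt_reference):
        rng = np.random.default_rng(17)
        treatment = sc.Treatment("LT", 0.0)
        sched = sc.random_k_schedule(rng, lo=0.8, hi=1.4)
        gt = sc.GroundTruth(k_schedules={treatment.label: sched},
                            allometry_params={"LT": (0.75, 5.0)}, noise_cv=0.08)
        records = sc.generate_harvests(gt, [treatment],
                                       {treatment.label: lt_reference},
                                       n_reps=4, seed=3)
        fit = sc.fit_allometry(records)[("LT", "nonstress")]
        wm = sc.measured_mass_series(records, fit=fit)
        mean_area = {
            d: float(np.mean([r.leaf_area for r in records if r.dafla == d]))
            for d in sc.HARVEST_DAYS}
        ks = sc.estimate_k(wm, lt_reference)
        report = sc.closure_run(ks, lt_reference, wm, fit=fit,
                                measured_area=mean_area)
        assert report["slope_within_ci"]


class TestDissection:
    def test_printed_table_worked_examples(self, reference_k_series):
        out = sc.dissect_k(reference_k_series)
        first = out.factors.iloc[0]
        assert round_half_up(first["k_ht"]) == 0.96     # 1.33 / 1.38
        assert round_half_up(first["k_40_LT"]) == 1.17  # 1.61 / 1.38
        assert round_half_up(first["k_80_HT"]) == 0.81  # 1.08 / 1.33

    def test_printed_table_reproduced_in_all_cells(self, reference_k_series):
        out = sc.dissect_k(reference_k_series)
        for col, expected in REFERENCE_K_FACTORS.items():
            got = [round_half_up(v) for v in out.factors[col]]
            assert got == list(expected), col

    def test_recomposition_identity(self, reference_k_series):
        out = sc.dissect_k(reference_k_series)
        raw = out.raw
        for _, frow in out.factors.iterrows():
            iv = (int(frow["start"]), int(frow["end"]))
            for _, rrow in raw[(raw["start"] == iv[0])].iterrows():
                k = recompose(frow, rrow["regime"], rrow["salinity"])
                assert k == pytest.approx(rrow["k"], rel=1e-12)

    @given(data=st.data())
    @hyp_seed(99)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_recomposition_identity_on_random_tables(self, data):
        ivs = INTERVALS[:3]
        table = {}
        for reg in ("LT", "HT"):
            for x in (0, 40, 80):
                ks = [data.draw(st.floats(0.2, 2.0)) for _ in ivs]
                table[(reg, x)] = {iv: k for iv, k in zip(ivs, ks)}
        out = sc.dissect_k(sc.KSeries.from_dict(table))
        for _, frow in out.factors.iterrows():
            iv = (int(frow["start"]), int(frow["end"]))
            for (reg, x), sched in table.items():
                assert recompose(frow, reg, float(x)) == \
                    pytest.approx(sched[iv], rel=1e-12)

    def test_all_equal_k_gives_unit_factors(self):
        table = {(reg, x): {iv: 0.9 for iv in INTERVALS}
                 for reg in ("LT", "HT") for x in (0, 40)}
        out = sc.dissect_k(sc.KSeries.from_dict(table))
        assert np.allclose(out.factors["k_ht"], 1.0)
        assert np.allclose(out.factors["k_40_LT"], 1.0)

    def test_missing_control_column_rejected(self):
        table = {("LT", 40): {iv: 1.0 for iv in INTERVALS}}
        with pytest.raises(ValueError, match="control"):
            sc.dissect_k(sc.KSeries.from_dict(table))


def test_round_half_up_matches_print_convention():
    assert round_half_up(0.955) == 0.96
    assert round_half_up(0.9649) == 0.96
    assert round_half_up(0.75) == 0.75
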