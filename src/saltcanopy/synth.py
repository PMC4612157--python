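"""Synthetic climate and harvest data with known ground truth.

Emulates the evaluation experiment's design: two greenhouse temperature
regimes (LT 22/18, HT 32/28 degC day/night), salinity 0/40/60/80 mM
NaCl applied at 21 DAFLA, destructive harvests of 4 replicates on
28-77 DAFLA, and a log-log allometric link between total leaf area and
shoot dry mass with multiplicative log-normal measurement noise.

"Measured" shoot masses are the forward simulation run with the
ground-truth relative light-use efficiency k_true in place of the
reference efficiency (exactly: the k = 1 reference trajectory with each
daily increment rescaled, which is the same thing by linearity), times
noise; leaf areas derive from the true masses through the ground-truth
allometry, times noise. The generator therefore carries a known k
schedule and known allometric coefficients for parameter-recovery
tests.

Climate: day temperature fluctuates around the regime target (SD 1 degC);
VPD is a linear function of day temperature plus noise, tuned to the
observed temperature-VPD correlation (R^2 ~ 0.71) with regime means of
~1.0 kPa (LT) and ~2.2 kPa (HT); PAR follows a seasonal sinusoid around
8 MJ m^-2 d^-1. The VPD and PAR magnitudes are package defaults chosen
as realistic spring-greenhouse values (not reported measurements) and
are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClimateDay, Treatment, HARVEST_DAYS, K_INTERVALS, REGIME_TEMPS
from .production import KSchedule, apply_k_schedule, harvest_masses

__all__ = [
    "HarvestRecord",
    "GroundTruth",
    "generate_climate",
    "generate_harvests",
    "harvests_to_frame",
    "frame_to_harvests",
    "random_k_schedule",
]

# VPD = VPD_INTERCEPT + VPD_SLOPE * t_day + noise; slope/noise give the
# target Pearson r ~ 0.84 (R^2 ~ 0.71) for t_day SD 1 degC, and regime
# means 1.0 kPa (22 degC) / 2.2 kPa (32 degC).
VPD_SLOPE = 0.12
VPD_INTERCEPT = -1.64
VPD_NOISE_SD = 0.0775


@dataclass(frozen=True)
class HarvestRecord:
    """One harvested plant: leaf area (cm2) and shoot dry mass (g)."""

    dafla: int
    replicate: int
    leaf_area: float
    shoot_mass: float
    treatment: Treatment

    def __post_init__(self) -> None:
        if self.leaf_area <= 0 or self.shoot_mass <= 0:
            raise ValueError("leaf_area and shoot_mass must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Known data-generating parameters of a synthetic experiment.

    ``k_schedules`` maps a treatment label (e.g. "LT-40") to the true
    interval-wise relative light-use efficiency; ``allometry_params``
    maps a regime to the true (p, q) of ln(A) = p ln(W_sh) + q;
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal measurement noise (mean-preserving).
    """

    k_schedules: dict
    allometry_params: dict
    noise_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for label, sched in self.k_schedules.items():
            vals = sched.intervals.values() if isinstance(sched, KSchedule) \
                else sched.values()
            if any(k <= 0 for k in vals):
                raise ValueError(f"all k must be > 0 (treatment {label})")

    def schedule_for(self, treatment: Treatment) -> KSchedule:
        sched = self.k_schedules.get(treatment.label, {})
        return sched if isinstance(sched, KSchedule) else KSchedule(sched)


def generate_climate(n_days: int, regime: str = "LT", seed: int = 0,
                     t_sd: float = 1.0, par_mean: float = 8.0,
                     par_rel_amp: float = 0.4, par_noise_sd: float = 1.0,
                     doy_start: int = 90) -> list[ClimateDay]:
    """Daily climate series for DAFLA 1..n_days under a regime."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    t_day_target, t_night_target = REGIME_TEMPS[regime]
    rng = np.random.default_rng(seed)
    days = []
    for d in range(1, n_days + 1):
        t_day = t_day_target + t_sd * rng.standard_normal()
        t_night = t_night_target + 0.7 * rng.standard_normal()
        vpd = VPD_INTERCEPT + VPD_SLOPE * t_day + VPD_NOISE_SD * rng.standard_normal()
        par = par_mean * (1.0 + par_rel_amp * math.sin(
            2.0 * math.pi * (doy_start + d - 80) / 365.0)) \
            + par_noise_sd * rng.standard_normal()
        days.append(ClimateDay(
            dafla=d, t_day=float(t_day), t_night=float(t_night),
            vpd=float(max(0.2, vpd)), par=float(max(0.5, par))))
    return days


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-preserving multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def generate_harvests(ground_truth: GroundTruth, treatments: list[Treatment],
                      references: dict, harvest_days=HARVEST_DAYS,
                      n_reps: int = 4, seed: int = 0) -> list[HarvestRecord]:
    """Manufacture "measured" harvest records for each treatment.

    ``references`` maps each treatment label to its k = 1 reference
    trajectory (from :func:`saltcanopy.production.simulate` under that
    treatment's architecture). Replicates are independent noise draws
    around the single k_true-scaled trajectory.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    cv = ground_truth.noise_cv
    records = []
    for tr in treatments:
        ref = references[tr.label]
        true_traj = apply_k_schedule(ref, ground_truth.schedule_for(tr))
        w_true = harvest_masses(true_traj, harvest_days)
        p, q = ground_truth.allometry_params[tr.regime]
        for day in harvest_days:
            w = w_true[day]
            a = math.exp(p * math.log(w) + q)
            mass_noise = _lognormal_factors(rng, cv, n_reps)
            area_noise = _lognormal_factors(rng, cv, n_reps)
            for r in range(n_reps):
                records.append(HarvestRecord(
                    dafla=int(day), replicate=r + 1,
                    leaf_area=a * float(area_noise[r]),
                    shoot_mass=w * float(mass_noise[r]),
                    treatment=tr))
    return records


def harvests_to_frame(records: list[HarvestRecord]) -> pd.DataFrame:
    """Tabulate records (dafla,replicate,regime,salinity,leaf_area_cm2,shoot_mass_g)."""
    return pd.DataFrame({
        "dafla": [r.dafla for r in records],
        "replicate": [r.replicate for r in records],
        "regime": [r.treatment.regime for r in records],
        "salinity": [r.treatment.salinity_x for r in records],
        "leaf_area_cm2": [r.leaf_area for r in records],
        "shoot_mass_g": [r.shoot_mass for r in records],
    })


def frame_to_harvests(frame: pd.DataFrame, salinity_start: int = 21) -> list[HarvestRecord]:
    return [
        HarvestRecord(
            dafla=int(r.dafla), replicate=int(r.replicate),
            leaf_area=float(r.leaf_area_cm2), shoot_mass=float(r.shoot_mass_g),
            treatment=Treatment(regime=str(r.regime), salinity_x=float(r.salinity),
                                salinity_start=salinity_start))
        for r in frame.itertuples(index=False)
    ]


def random_k_schedule(rng: np.random.Generator, lo: float = 0.3,
                      hi: float = 1.8, intervals=K_INTERVALS) -> KSchedule:
    """Random ground-truth k schedule for recovery experiments."""
    return KSchedule({iv: float(rng.uniform(lo, hi)) for iv in intervals})
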