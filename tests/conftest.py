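"""Shared fixtures: small canopies, climates, and one reference simulation.

The reference k table below is the published interval-wise relative
canopy light-use efficiency of the tomato salinity x temperature
evaluation experiment (upper block: raw k_T,x per regime and salinity;
expected factors: the printed dissection into k_HT and k_x at 2-decimal
rounding). It serves as a worked-example input for the dissection
algebra.
"""

from __future__ import annotations

import numpy as np
import pytest

import saltcanopy as sc

INTERVALS = ((29, 35), (36, 43), (44, 50), (51, 56), (57, 63), (64, 70), (71, 77))

#: Raw k_T,x: {(regime, salinity): (k per interval)}
REFERENCE_K_RAW = {
    ("LT", 0): (1.38, 1.60, 1.02, 1.16, 0.70, 1.18, 0.86),
    ("HT", 0): (1.33, 1.59, 0.91, 0.88, 0.49, 0.76, 0.71),
    ("LT", 40): (1.61, 1.76, 1.07, 1.24, 0.68, 1.24, 0.80),
    ("HT", 40): (1.42, 1.69, 0.93, 0.90, 0.46, 0.80, 0.68),
    ("LT", 60): (1.32, 1.41, 0.87, 1.00, 0.55, 0.86, 0.65),
    ("HT", 60): (1.24, 1.45, 0.78, 0.75, 0.39, 0.68, 0.59),
    ("LT", 80): (1.10, 1.10, 0.69, 0.77, 0.45, 0.78, 0.52),
    ("HT", 80): (1.08, 1.24, 0.66, 0.63, 0.33, 0.57, 0.50),
}

#: Printed dissected factors at 2 decimals: column -> per-interval values.
REFERENCE_K_FACTORS = {
    "k_ht": (0.96, 0.99, 0.89, 0.76, 0.70, 0.64, 0.83),
    "k_40_LT": (1.17, 1.10, 1.05, 1.07, 0.97, 1.05, 0.93),
    "k_40_HT": (1.07, 1.06, 1.02, 1.02, 0.94, 1.05, 0.96),
    "k_60_LT": (0.96, 0.88, 0.85, 0.86, 0.79, 0.73, 0.76),
    "k_60_HT": (0.93, 0.91, 0.86, 0.85, 0.80, 0.89, 0.83),
    "k_80_LT": (0.80, 0.69, 0.68, 0.66, 0.64, 0.66, 0.60),
    "k_80_HT": (0.81, 0.78, 0.73, 0.72, 0.67, 0.75, 0.70),
}

#: Published whole-period (29-77) architectural / non-architectural
#: effects (%) per regime and salinity, and the measured whole-period
#: shoot-mass reductions they should sum to (LT-40).
REFERENCE_EFFECTS_WHOLE = {
    ("LT", 40): (8.8, -2.7),
    ("HT", 80): (21.9, 19.0),
}


@pytest.fixture(scope="session")
def reference_k_series() -> sc.KSeries:
    table = {key: {iv: k for iv, k in zip(INTERVALS, vals)}
             for key, vals in REFERENCE_K_RAW.items()}
    return sc.KSeries.from_dict(table)


@pytest.fixture(scope="session")
def params() -> sc.GrowthParams:
    return sc.GrowthParams()


@pytest.fixture(scope="session")
def lt_climate():
    return sc.generate_climate(77, regime="LT", seed=1)


@pytest.fixture(scope="session")
def lt_reference(params, lt_climate):
    """Control (0 mM) LT reference trajectory, k = 1, modest ray count."""
    return sc.simulate(params=params, climate=lt_climate,
                       treatment=sc.Treatment("LT", 0.0),
                       n_rays=2000, seed=0)


@pytest.fixture(scope="session")
def salt80_reference(params, lt_climate):
    """80 mM LT reference trajectory with the same seeds."""
    return sc.simulate(params=params, climate=lt_climate,
                       treatment=sc.Treatment("LT", 80.0),
                       n_rays=2000, seed=0)


@pytest.fixture(scope="session")
def day77_mesh(params, lt_climate):
    canopy = sc.init_canopy(params, seed=0)
    for day in lt_climate:
        sc.step_day(canopy, day, sc.Treatment("LT", 0.0), params)
    return sc.to_mesh(canopy)
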