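"""Sensitivity of dry mass production to architectural traits.

One trait is perturbed at a time — leaf number (via the phyllochron),
the salinity sensitivity of leaf elongation (c_El,max), potential
internode length, or leaf insertion angle — and the canopy is re-run
under the scenario's stressed light-use efficiency k_T,x * eps. Results
are normalised to the unperturbed reference run with the same seed:
relative shoot dry mass, relative total leaf area, and canopy light
transmittance Q_T/Q_0 on the final day. Whole-period canopy light
interception (PAR-weighted absorbed fraction) supports the regression
of dry-mass change on interception change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .architecture import GrowthParams, apply_trait_scaling, salinity_trait_factor
from .core import Treatment
from .production import KSchedule, apply_k_schedule, simulate

__all__ = ["scan", "interception_regression", "salinity_trait_factor"]

#: Published scan grids: per-10-mM reduction rates (leaf number,
#: internode) and multiplicative factor grids (c_El,max, leaf angle).
TRAIT_GRIDS = {
    "leaf_number": (0.03, 0.06, 0.09),      # reduction per 10 mM NaCl
    "internode_length": (0.02, 0.04, 0.06),  # reduction per 10 mM NaCl
    "c_el_max": (0.5, 0.75, 1.25, 1.5),      # x reference value
    "leaf_angle": (0.70, 0.85, 1.15, 1.30),  # x reference angles
}


def _summarise(traj: pd.DataFrame, climate) -> dict:
    par = np.array([d.par for d in climate])
    interception = float(np.sum(traj["interception"].to_numpy() * par) / par.sum())
    last = traj.iloc[-1]
    return {
        "w_sh": float(last["w_sh"]),
        "a_s": float(last["leaf_area_cm2"]),
        "transmittance": float(last["transmittance"]),
        "interception": interception,
    }


def scan(trait: str, levels, treatment: Treatment, *, params=None,
         climate=None, lue=None, k_stressed: dict | KSchedule | None = None,
         seed: int = 0, n_rays: int = 5000, **sim_kwargs) -> pd.DataFrame:
    """Scan one architectural trait under a salinity x temperature scenario.

    ``levels`` are trait factors (1.0 = reference); use
    :func:`salinity_trait_factor` to convert per-10-mM reduction rates
    into overall factors at the scenario's salinity. Every level —
    plus the reference level 1.0 — is simulated with the same seed and
    the stressed efficiency k_T,x * eps; outputs are percentages of the
    reference run.
    """
    if trait not in TRAIT_GRIDS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {sorted(TRAIT_GRIDS)}")
    k_stressed = k_stressed if k_stressed is not None else {}
    base = params or GrowthParams()

    def run(level: float) -> dict:
        p = apply_trait_scaling(base, trait, level)
        traj = simulate(params=p, climate=climate, treatment=treatment, lue=lue,
                        n_rays=n_rays, seed=seed, **sim_kwargs)
        return _summarise(apply_k_schedule(traj, k_stressed), climate)

    ref = run(1.0)
    rows = []
    for level in levels:
        s = run(float(level))
        rows.append({
            "trait": trait, "level": float(level),
            "regime": treatment.regime, "salinity": treatment.salinity_x,
            "w_sh_rel": 100.0 * s["w_sh"] / ref["w_sh"],
            "a_s_rel": 100.0 * s["a_s"] / ref["a_s"],
            "transmittance_pct": 100.0 * s["transmittance"],
            "interception": s["interception"],
            "w_sh": s["w_sh"], "a_s": s["a_s"],
        })
    out = pd.DataFrame(rows)
    out.attrs["reference"] = ref
    return out


def interception_regression(results: pd.DataFrame,
                            reference_interception: float) -> tuple[float, float]:
    """OLS of dry-mass change on light-interception change across scan points.

    Both variables are percentage deviations from the reference run.
    Returns (slope, R^2).
    """
    if len(results) < 5:
        raise ValueError("need at least 5 scan points for the regression")
    dx = 100.0 * (results["interception"].to_numpy() / reference_interception - 1.0)
    dy = results["w_sh_rel"].to_numpy() - 100.0
    if float(np.var(dx)) == 0.0:
        raise ValueError("degenerate regression: interception does not vary")
    res = sm.OLS(dy, sm.add_constant(dx)).fit()
    return float(res.params[1]), float(res.rsquared)
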