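"""Log-log allometry between total leaf area and shoot dry mass.

The relationship ln(A) = p ln(W_sh) + q is fitted by ordinary least
squares of ln(area) on ln(mass) — the direction in which the equation
is written, not reduced major axis. Fits are made separately for the
LT and HT temperature regimes, and separately for non-stressed plants
and for plants under salinity with salt levels pooled (salinity barely
shifts this allometry, temperature does).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["AllometryFit", "fit_loglog", "fit_allometry",
           "mass_from_area", "area_from_mass"]


@dataclass(frozen=True)
class AllometryFit:
    """OLS fit of ln(A) on ln(W_sh): slope p, intercept q."""

    p: float
    q: float
    r2: float
    p_value: float
    n: int
    group: tuple = ()
    p_se: float = float("nan")
    q_se: float = float("nan")

    def ci95_contains(self, p_true: float, q_true: float) -> bool:
        """Whether (p_true, q_true) lie in the marginal 95% intervals."""
        return (abs(self.p - p_true) <= 1.96 * self.p_se
                and abs(self.q - q_true) <= 1.96 * self.q_se)


def fit_loglog(shoot_mass, leaf_area, group: tuple = ()) -> AllometryFit:
    """Fit ln(leaf_area) = p ln(shoot_mass) + q by OLS."""
    w = np.asarray(shoot_mass, dtype=float)
    a = np.asarray(leaf_area, dtype=float)
    if w.size < 3:
        raise ValueError(f"need >= 3 records to fit allometry, got {w.size}")
    bad = np.where((w <= 0) | (a <= 0))[0]
    if bad.size:
        raise ValueError(f"non-positive mass/area at record index {bad[0]}")
    X = sm.add_constant(np.log(w))
    res = sm.OLS(np.log(a), X).fit()
    return AllometryFit(
        p=float(res.params[1]), q=float(res.params[0]),
        r2=float(res.rsquared) if w.size > 2 else 1.0,
        p_value=float(res.pvalues[1]),
        n=int(w.size), group=group,
        p_se=float(res.bse[1]), q_se=float(res.bse[0]))


def fit_allometry(records, pool: str = "stress") -> dict:
    """Fit the allometry per group from harvest records.

    Groups are {LT, HT} x {non-stress, salt-pooled}: keys
    (regime, "nonstress") for salinity 0 and (regime, "salt") for all
    positive salinities pooled. Only groups with data are returned; a
    present group with fewer than 3 records raises.
    """
    groups: dict[tuple, list] = {}
    for r in records:
        stress = "nonstress" if r.treatment.salinity_x == 0 else "salt"
        groups.setdefault((r.treatment.regime, stress), []).append(r)
    fits = {}
    for key, recs in sorted(groups.items()):
        fits[key] = fit_loglog([r.shoot_mass for r in recs],
                               [r.leaf_area for r in recs], group=key)
    return fits


def mass_from_area(leaf_area: float, fit: AllometryFit) -> float:
    """Invert the allometry: W_sh = exp((ln A - q) / p)."""
    if not leaf_area > 0:
        raise ValueError("leaf_area must be > 0")
    return float(np.exp((np.log(leaf_area) - fit.q) / fit.p))


def area_from_mass(shoot_mass: float, fit: AllometryFit) -> float:
    """Forward allometry: A = exp(p ln W_sh + q)."""
    if not shoot_mass > 0:
        raise ValueError("shoot_mass must be > 0")
    return float(np.exp(fit.p * np.log(shoot_mass) + fit.q))
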