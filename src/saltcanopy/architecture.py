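"""3D tomato canopy: procedural construction and daily growth.

The canopy holds 16 plants on a 4 x 4 grid at 1 m spacing. A plant is a
stack of phytomers (internode + leaf); each leaf carries seven flat
rhombus leaflets along a drooping rachis, with a phyllotaxis angle of
144 deg (optionally jittered by +-10 deg per phytomer).

Organ elongation is driven by thermal time and modified multiplicatively
by day temperature, vapour pressure deficit and salinity:

    rate = potential(age) * g_T(t_day) * g_V(vpd) * g_S(x, vpd)

The potential elongation follows a beta-shaped rate over a fixed
thermal-time expansion window (peak rate at mid-expansion), so the final
organ length is the potential maximum scaled down by the environmental
modifiers experienced during expansion. Salinity suppresses leaf
elongation in proportion to concentration x VPD,
g_S = max(0, 1 + c_el_max * x * vpd), and — matching the empirical
finding for tomato — leaves internode elongation untouched (g_S = 1).

All response forms are intentionally simple stand-ins with the right
causal structure (temperature optimum near 25 degC, VPD suppression
above 1 kPa); they are plain module functions and can be swapped by
passing a modified :class:`GrowthParams`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import ClimateDay, Treatment

__all__ = [
    "GrowthParams",
    "Plant",
    "Canopy",
    "Mesh",
    "init_canopy",
    "organ_elongation",
    "step_day",
    "apply_trait_scaling",
    "salinity_trait_factor",
    "to_mesh",
    "total_leaf_area",
    "plant_height",
    "leaf_number",
    "g_temperature",
    "g_vpd",
    "g_salinity",
]

#: Leaflet positions along the rachis (fraction of leaf length). Three
#: opposite pairs plus the terminal leaflet.
_LEAFLET_FRACTIONS = np.array([0.30, 0.30, 0.55, 0.55, 0.80, 0.80, 1.00])
_LEAFLET_SIDES = np.array([1, -1, 1, -1, 1, -1, 0])  # 0 = terminal
#: Relative leaflet lengths before area normalisation (terminal largest).
_LEAFLET_WEIGHTS = np.array([0.55, 0.55, 0.70, 0.70, 0.85, 0.85, 1.00])
#: Angle between lateral leaflet axis and the rachis tangent (deg).
_LATERAL_ANGLE_DEG = 60.0


@dataclass(frozen=True)
class GrowthParams:
    """Architectural and growth parameters of the virtual tomato.

    Lengths in cm, angles in degrees, thermal time in degC d (base
    ``t_base``). ``c_el_max`` (mM^-1 kPa^-1, <= 0) is the sensitivity of
    leaf elongation to salinity; the reference value -0.0006 is the
    midpoint of the published sensitivity-scan grid (50-150% of
    reference) and is flagged as inferred rather than measured.
    """

    phyllochron_dd: float = 25.0
    t_base: float = 10.0
    l_max: float = 40.0
    leaf_dur_dd: float = 250.0
    c_el_max: float = -0.0006
    i_max: float = 6.0
    internode_dur_dd: float = 150.0
    theta_insertion_deg: float = 35.0
    curvature_deg: float = 70.0
    leaflet_aspect: float = 0.6
    blade_area_coeff: float = 0.4375  # blade area = coeff * length^2 (40 cm -> 700 cm2)
    phyllotaxis_deg: float = 144.0
    phyllotaxis_jitter_deg: float = 10.0
    sla: float = 200.0  # cm2 g^-1, bookkeeping only
    # trait-scan multipliers (1.0 = reference architecture)
    leaf_number_factor: float = 1.0
    angle_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.l_max <= 0:
            raise ValueError("l_max must be > 0")
        if self.i_max < 0:
            raise ValueError("i_max must be >= 0")
        if not (0 < self.leaflet_aspect < 2):
            raise ValueError("leaflet_aspect must be in (0, 2)")
        if self.c_el_max > 0:
            raise ValueError("c_el_max must be <= 0")
        if self.leaf_number_factor <= 0:
            raise ValueError("leaf_number_factor must be > 0")

    @property
    def ler_max(self) -> float:
        """Peak potential leaf elongation rate (cm d^-1 at 10 degC d d^-1)."""
        return 15.0 * self.l_max / self.leaf_dur_dd

    @property
    def ier_max(self) -> float:
        """Peak potential internode elongation rate (cm d^-1 at 10 degC d d^-1)."""
        return 15.0 * self.i_max / self.internode_dur_dd

    @property
    def phyllochron_effective(self) -> float:
        """Phyllochron after leaf-number trait scaling (fewer leaves <=> longer)."""
        return self.phyllochron_dd / self.leaf_number_factor

    def leaflet_scale(self) -> np.ndarray:
        """Leaflet lengths as fractions of leaf length, normalised so the
        seven rhombus areas sum exactly to ``blade_area_coeff * L^2``."""
        target = 2.0 * self.blade_area_coeff / self.leaflet_aspect
        scale = math.sqrt(target / float(np.sum(_LEAFLET_WEIGHTS**2)))
        return _LEAFLET_WEIGHTS * scale


# ---------------------------------------------------------------------------
# growth-response functions (stand-in forms, see module docstring)
# ---------------------------------------------------------------------------

def g_temperature(t_day: float, t_min: float = 5.0, t_opt: float = 25.0,
                  t_max: float = 40.0) -> float:
    """Optimum-shaped temperature response, 1 at ``t_opt``, 0 outside."""
    if t_day <= t_min or t_day >= t_max:
        return 0.0
    q = (t_opt - t_min) / (t_max - t_opt)
    g = ((t_max - t_day) / (t_max - t_opt)) * ((t_day - t_min) / (t_opt - t_min)) ** q
    return float(min(max(g, 0.0), 1.0))


def g_vpd(vpd: float, threshold: float = 1.0, slope: float = 0.2,
          floor: float = 0.5) -> float:
    """Linear suppression of elongation above ``threshold`` kPa, floored."""
    return float(min(1.0, max(floor, 1.0 - slope * (vpd - threshold))))


def g_salinity(salinity_x: float, vpd: float, c_el_max: float) -> float:
    """Salinity x VPD suppression of leaf elongation, clipped at 0."""
    if salinity_x < 0:
        raise ValueError("salinity must be >= 0")
    return float(max(0.0, 1.0 + c_el_max * salinity_x * vpd))


def _beta_cdf(u: float) -> float:
    """Integral of the 6u(1-u) rate shape: fraction of potential length."""
    u = min(max(u, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


def _potential_increment(age_dd: float, dd: float, final_len: float,
                         dur_dd: float) -> float:
    """Potential elongation (cm) over one day of ``dd`` thermal time."""
    f0 = _beta_cdf(age_dd / dur_dd)
    f1 = _beta_cdf((age_dd + dd) / dur_dd)
    return final_len * (f1 - f0)


def organ_elongation(organ_kind: str, age_dd: float, climate: ClimateDay,
                     salinity_x: float, params: GrowthParams) -> float:
    """Daily elongation (cm d^-1) of a leaf or internode.

    Salinity acts on leaves only; internode elongation is unaffected by
    salinity at any concentration.
    """
    if age_dd < 0:
        raise ValueError("age_dd must be >= 0")
    if salinity_x < 0:
        raise ValueError("salinity must be >= 0")
    if organ_kind not in ("leaf", "internode"):
        raise ValueError(f"unknown organ kind {organ_kind!r}")
    dd = max(0.0, climate.t_mean - params.t_base)
    env = g_temperature(climate.t_day) * g_vpd(climate.vpd)
    if organ_kind == "leaf":
        pot = _potential_increment(age_dd, dd, params.l_max, params.leaf_dur_dd)
        env *= g_salinity(salinity_x, climate.vpd, params.c_el_max)
    else:
        pot = _potential_increment(age_dd, dd, params.i_max, params.internode_dur_dd)
    return pot * env


# ---------------------------------------------------------------------------
# canopy state
# ---------------------------------------------------------------------------

@dataclass
class Plant:
    """One plant: parallel per-phytomer arrays (rank order, index 0 = oldest)."""

    x: float
    y: float
    azimuths: list[float] = field(default_factory=list)
    leaf_len: list[float] = field(default_factory=list)
    leaf_age: list[float] = field(default_factory=list)
    int_len: list[float] = field(default_factory=list)
    int_age: list[float] = field(default_factory=list)
    cum_dd: float = 0.0

    @property
    def n_phytomers(self) -> int:
        return len(self.azimuths)


@dataclass
class Canopy:
    """Whole-stand state: plants, parameters and the day counter."""

    params: GrowthParams
    plants: list[Plant]
    dafla: int = 0
    _rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    @property
    def ground_rect(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the reflective ground, metres."""
        xs = [p.x for p in self.plants]
        ys = [p.y for p in self.plants]
        m = 0.5
        return (min(xs) - m, max(xs) + m, min(ys) - m, max(ys) + m)


def init_canopy(params: GrowthParams | None = None, seed: int = 0,
                n_rows: int = 4, n_cols: int = 4, spacing: float = 1.0) -> Canopy:
    """16-plant (4 x 4, 1 m spacing) canopy with one phytomer per plant.

    Each plant gets a random base azimuth; subsequent leaves rotate by
    the phyllotaxis angle plus a uniform jitter on
    [-jitter, +jitter] deg, all drawn from a generator seeded here.
    """
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    plants = []
    for i in range(n_rows):
        for j in range(n_cols):
            p = Plant(x=float(i * spacing), y=float(j * spacing))
            p.azimuths.append(float(rng.uniform(0.0, 360.0)))
            p.leaf_len.append(0.0)
            p.leaf_age.append(0.0)
            p.int_len.append(0.0)
            p.int_age.append(0.0)
            plants.append(p)
    return Canopy(params=params, plants=plants, _rng=rng)


def step_day(canopy: Canopy, climate: ClimateDay, treatment: Treatment,
             params: GrowthParams | None = None) -> Canopy:
    """Advance the canopy by one day (in place; the canopy is returned).

    New phytomers appear when cumulative thermal time crosses phyllochron
    multiples; every extant organ elongates per :func:`organ_elongation`.
    Salinity acts only from ``treatment.salinity_start`` onward.
    """
    params = params or canopy.params
    if climate.dafla != canopy.dafla + 1:
        raise ValueError(
            f"climate day {climate.dafla} does not follow canopy day {canopy.dafla}"
        )
    dd = max(0.0, climate.t_mean - params.t_base)
    x = treatment.active_salinity(climate.dafla)
    env = g_temperature(climate.t_day) * g_vpd(climate.vpd)
    env_leaf = env * g_salinity(x, climate.vpd, params.c_el_max)
    jit = params.phyllotaxis_jitter_deg
    phyllo = params.phyllochron_effective
    for plant in canopy.plants:
        plant.cum_dd += dd
        while plant.n_phytomers < 1 + int(plant.cum_dd / phyllo):
            delta = params.phyllotaxis_deg + jit * float(canopy._rng.uniform(-1.0, 1.0))
            plant.azimuths.append((plant.azimuths[-1] + delta) % 360.0)
            plant.leaf_len.append(0.0)
            plant.leaf_age.append(0.0)
            plant.int_len.append(0.0)
            plant.int_age.append(0.0)
        for r in range(plant.n_phytomers):
            plant.leaf_len[r] += env_leaf * _potential_increment(
                plant.leaf_age[r], dd, params.l_max, params.leaf_dur_dd)
            plant.leaf_len[r] = min(plant.leaf_len[r], params.l_max)
            plant.leaf_age[r] += dd
            plant.int_len[r] += env * _potential_increment(
                plant.int_age[r], dd, params.i_max, params.internode_dur_dd)
            plant.int_len[r] = min(plant.int_len[r], params.i_max)
            plant.int_age[r] += dd
    canopy.dafla += 1
    return canopy


# ---------------------------------------------------------------------------
# trait scaling for the sensitivity scans
# ---------------------------------------------------------------------------

_TRAITS = ("leaf_number", "c_el_max", "internode_length", "leaf_angle")


def apply_trait_scaling(params: GrowthParams, trait: str, factor: float) -> GrowthParams:
    """Return a copy of ``params`` with exactly one trait scaled.

    * ``leaf_number``: factor f scales the final leaf count (implemented
      as phyllochron / f, so f = 0.88 means 12% fewer leaves).
    * ``c_el_max``: multiplies the salinity sensitivity of leaf elongation.
    * ``internode_length``: multiplies the potential internode length.
    * ``leaf_angle``: multiplies the leaf insertion elevation angle.
    """
    if trait == "leaf_number":
        return dataclasses.replace(params, leaf_number_factor=factor)
    if trait == "c_el_max":
        return dataclasses.replace(params, c_el_max=params.c_el_max * factor)
    if trait == "internode_length":
        return dataclasses.replace(params, i_max=params.i_max * factor)
    if trait == "leaf_angle":
        return dataclasses.replace(params, angle_factor=factor)
    raise ValueError(f"unknown trait {trait!r}; expected one of {_TRAITS}")


def salinity_trait_factor(reduction_per_10mm: float, salinity_x: float) -> float:
    """Overall trait factor from a per-10-mM reduction rate.

    E.g. 3% per 10 mM at 40 mM NaCl -> 1 - 0.03*4 = 0.88.
    """
    return 1.0 - reduction_per_10mm * salinity_x / 10.0


# ---------------------------------------------------------------------------
# geometry / mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Triangle soup for the light model (metres).

    ``triangles`` is (n, 3, 3); ``surface_id`` maps each triangle to a
    leaflet (or the ground surface); ``is_ground`` flags ground
    triangles. ``surface_area`` (m^2) is indexed by surface id; leaf
    surfaces come first, the ground surface (if present) last.
    """

    triangles: np.ndarray
    surface_id: np.ndarray
    is_ground: np.ndarray
    surface_area: np.ndarray
    n_leaf_surfaces: int
    block_ranges: np.ndarray  # (B, 2) triangle index ranges per leaf (+ ground)
    group_blocks: np.ndarray  # (G, 2) block index ranges per plant (+ ground)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def leaf_area_m2(self) -> float:
        return float(np.sum(self.surface_area[: self.n_leaf_surfaces]))

    def triangle_areas(self) -> np.ndarray:
        e1 = self.triangles[:, 1] - self.triangles[:, 0]
        e2 = self.triangles[:, 2] - self.triangles[:, 0]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def _leaf_geometry(base: np.ndarray, azimuth_deg: float, length_cm: float,
                   params: GrowthParams,
                   lam: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Triangles (14, 3, 3) and leaflet areas (7,) for one leaf, metres.

    The rachis starts at ``base`` with elevation
    ``theta_insertion * angle_factor`` above horizontal and droops
    progressively by ``curvature_deg`` from base to tip. Each leaflet is
    a flat rhombus (two triangles, long diagonal = leaflet length).
    """
    L = length_cm / 100.0
    # the angle trait scales the whole elevation profile (insertion and
    # droop together), so factor > 1 steepens the leaf everywhere
    theta0 = math.radians(params.theta_insertion_deg * params.angle_factor)
    droop = math.radians(params.curvature_deg * params.angle_factor)
    phi = math.radians(azimuth_deg)
    hx, hy = math.cos(phi), math.sin(phi)   # horizontal heading
    bx, by = -hy, hx                        # horizontal, perp to rachis

    # integrate the curved rachis to the leaflet attachment points
    # (exact arc of the continuously drooping tangent)
    def _arc(f: float) -> tuple[float, float]:
        # planar arc length components: integral of (cos th, sin th) df
        if droop < 1e-9:
            return f * math.cos(theta0), f * math.sin(theta0)
        th = theta0 - droop * f
        r = (math.sin(theta0) - math.sin(th)) / droop
        z = (math.cos(th) - math.cos(theta0)) / droop
        return r, z

    if lam is None:
        lam = params.leaflet_scale()
    tris = np.empty((14, 3, 3))
    areas = np.empty(7)
    ca = math.cos(math.radians(_LATERAL_ANGLE_DEG))
    sa = math.sin(math.radians(_LATERAL_ANGLE_DEG))
    b0x, b0y, b0z = float(base[0]), float(base[1]), float(base[2])
    for i in range(7):
        f = float(_LEAFLET_FRACTIONS[i])
        rr, zz = _arc(f)
        px = b0x + L * rr * hx
        py = b0y + L * rr * hy
        pz = b0z + L * zz
        th = theta0 - droop * f
        ct, st = math.cos(th), math.sin(th)
        tx, ty, tz = ct * hx, ct * hy, st      # rachis tangent
        # leaf-plane normal n = t x b (unit: t and b orthonormal)
        nx = -tz * by
        ny = tz * bx
        nz = tx * by - ty * bx
        side = int(_LEAFLET_SIDES[i])
        if side == 0:
            ux, uy, uz = tx, ty, tz
        else:
            ux = ca * tx + side * sa * bx
            uy = ca * ty + side * sa * by
            uz = ca * tz
        # v = n x u (in-plane width direction, unit)
        vx = ny * uz - nz * uy
        vy = nz * ux - nx * uz
        vz = nx * uy - ny * ux
        ell = lam[i] * L
        w = params.leaflet_aspect * ell
        he, hw = 0.5 * ell, 0.5 * w
        tipx, tipy, tipz = px + ell * ux, py + ell * uy, pz + ell * uz
        m1x, m1y, m1z = px + he * ux + hw * vx, py + he * uy + hw * vy, pz + he * uz + hw * vz
        m2x, m2y, m2z = px + he * ux - hw * vx, py + he * uy - hw * vy, pz + he * uz - hw * vz
        tris[2 * i, 0] = (px, py, pz)
        tris[2 * i, 1] = (tipx, tipy, tipz)
        tris[2 * i, 2] = (m1x, m1y, m1z)
        tris[2 * i + 1, 0] = (px, py, pz)
        tris[2 * i + 1, 1] = (m2x, m2y, m2z)
        tris[2 * i + 1, 2] = (tipx, tipy, tipz)
        areas[i] = 0.5 * ell * w
    return tris, areas


def to_mesh(canopy: Canopy, include_ground: bool = True,
            min_leaf_cm: float = 1e-4) -> Mesh:
    """Triangulate the canopy (leaflets + reflective ground).

    Leaves shorter than ``min_leaf_cm`` are skipped (degenerate
    geometry); their blade area is negligible. The summed one-sided
    triangle area of the leaf surfaces equals the bookkept total leaf
    area of the meshed leaves to float precision.
    """
    params = canopy.params
    lam = params.leaflet_scale()
    tri_list, area_list, block_ranges, group_blocks = [], [], [], []
    n_tris = 0
    for plant in canopy.plants:
        b_start = len(block_ranges)
        base_z = 0.0
        for r in range(plant.n_phytomers):
            base_z += plant.int_len[r] / 100.0
            L = plant.leaf_len[r]
            if L < min_leaf_cm:
                continue
            base = np.array([plant.x, plant.y, base_z])
            tris, areas = _leaf_geometry(base, plant.azimuths[r], L, params, lam)
            tri_list.append(tris)
            area_list.append(areas)
            block_ranges.append((n_tris, n_tris + 14))
            n_tris += 14
        group_blocks.append((b_start, len(block_ranges)))

    if tri_list:
        triangles = np.concatenate(tri_list, axis=0)
        areas = np.concatenate(area_list)
    else:
        triangles = np.zeros((0, 3, 3))
        areas = np.zeros(0)
    n_leaf_surfaces = len(areas)
    surface_id = np.repeat(np.arange(n_leaf_surfaces), 2)
    is_ground = np.zeros(len(triangles), dtype=bool)

    if include_ground:
        x0, x1, y0, y1 = canopy.ground_rect
        g = np.array([
            [[x0, y0, 0.0], [x1, y0, 0.0], [x1, y1, 0.0]],
            [[x0, y0, 0.0], [x1, y1, 0.0], [x0, y1, 0.0]],
        ])
        triangles = np.concatenate([triangles, g], axis=0)
        surface_id = np.concatenate([surface_id, [n_leaf_surfaces, n_leaf_surfaces]])
        is_ground = np.concatenate([is_ground, [True, True]])
        areas = np.concatenate([areas, [(x1 - x0) * (y1 - y0)]])
        block_ranges.append((len(triangles) - 2, len(triangles)))
        group_blocks.append((len(block_ranges) - 1, len(block_ranges)))

    return Mesh(
        triangles=np.ascontiguousarray(triangles, dtype=np.float64),
        surface_id=np.asarray(surface_id, dtype=np.int64),
        is_ground=is_ground,
        surface_area=areas,
        n_leaf_surfaces=n_leaf_surfaces,
        block_ranges=np.asarray(block_ranges, dtype=np.int64).reshape(-1, 2),
        group_blocks=np.asarray(group_blocks, dtype=np.int64).reshape(-1, 2),
    )


def total_leaf_area(canopy: Canopy, per_plant: bool = False):
    """Total blade area, cm^2 plant^-1 (mean over plants, or per plant).

    Blade area of a leaf of length L is ``blade_area_coeff * L^2``, the
    exact sum of its seven rhombus leaflet areas.
    """
    s = canopy.params.blade_area_coeff
    per = np.array([s * float(np.sum(np.square(p.leaf_len))) for p in canopy.plants])
    return per if per_plant else float(per.mean())


def plant_height(plant: Plant) -> float:
    """Plant height (cm): the sum of all internode lengths."""
    return float(sum(plant.int_len))


def leaf_number(plant: Plant) -> int:
    return plant.n_phytomers
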