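"""Sky dome construction and Monte Carlo canopy light interception.

The daily light source is a discretised hemispherical dome: ring-banded
diffuse patches (uniform or standard overcast radiance) plus a direct
component that follows the solar path for the site and date. Rays are
emitted downward from a horizontal plane just above the canopy,
stratified over dome directions, and traced through the leaflet mesh
with side-specific reflectance/transmittance and a diffusely reflective
ground. Open lateral boundaries: rays leaving the scene escape. The
emission rectangle extends beyond the measured ground rectangle by a
configurable margin so oblique light also enters from outside the plot
footprint (the residual edge bias of a finite margin is documented in
the methods note).

Outputs are collected in an :class:`AbsorptionMap`: per-leaflet absorbed
flux I_abs (J m^-2 d^-1), ground absorption, escaped flux and the canopy
transmittance Q_T/Q_0 (flux density reaching the ground over flux
density incident above the canopy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._tracer import trace_kernel
from .architecture import Mesh

__all__ = [
    "OpticalProps",
    "SkyDome",
    "AbsorptionMap",
    "build_sky",
    "solar_declination",
    "max_solar_elevation",
    "trace",
    "canopy_transmittance",
    "simple_scene",
]

MJ = 1.0e6


@dataclass(frozen=True)
class OpticalProps:
    """Side-specific leaf and ground optical coefficients (fractions).

    Defaults are the measured tomato values: adaxial/abaxial reflectance
    7.3%/12.7%, transmittance 2.4%/2.5%; the ground reflects 80% of
    incident light without transmittance.
    """

    adaxial_reflect: float = 0.073
    abaxial_reflect: float = 0.127
    adaxial_transmit: float = 0.024
    abaxial_transmit: float = 0.025
    ground_reflect: float = 0.80
    ground_transmit: float = 0.0

    def __post_init__(self) -> None:
        pairs = [
            (self.adaxial_reflect, self.adaxial_transmit),
            (self.abaxial_reflect, self.abaxial_transmit),
            (self.ground_reflect, self.ground_transmit),
        ]
        for rho, tau in pairs:
            if not (0 <= rho <= 1 and 0 <= tau <= 1 and rho + tau <= 1):
                raise ValueError("reflect/transmit must lie in [0,1] with sum <= 1")


@dataclass(frozen=True)
class SkyDome:
    """Discretised sky: downward unit directions with weights summing to 1.

    Weights are on a horizontal-irradiance basis: a patch's weight is the
    fraction of the daily PAR it delivers to an unobstructed horizontal
    surface.
    """

    directions: np.ndarray
    weights: np.ndarray
    latitude: float = float("nan")
    longitude: float = float("nan")
    day_of_year: int = 0
    diffuse_fraction: float = float("nan")

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(d[:, 2] >= 0):
            raise ValueError("all sky directions must point downward")
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def beam(cls, direction=(0.0, 0.0, -1.0)) -> "SkyDome":
        """Single-direction collimated source (unit weight)."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return cls(directions=d[None, :], weights=np.array([1.0]))


def solar_declination(day_of_year: int) -> float:
    """Solar declination (degrees) from the day of year."""
    return 23.45 * math.sin(math.radians(360.0 * (284 + day_of_year) / 365.0))


def max_solar_elevation(latitude: float, day_of_year: int) -> float:
    """Noon solar elevation (degrees) at a latitude and date."""
    return 90.0 - abs(latitude - solar_declination(day_of_year))


def _diffuse_band_weight(e1: float, e2: float, kind: str) -> float:
    """Horizontal-irradiance weight of the elevation band [e1, e2] (rad).

    Uniform overcast (uoc): radiance constant; standard overcast (soc):
    radiance proportional to (1 + 2 sin e)/3. Closed-form integrals of
    L(e) sin(e) cos(e) de (azimuth-integrated separately).
    """
    s1, s2 = math.sin(e1), math.sin(e2)
    if kind == "uoc":
        return 0.5 * (s2 * s2 - s1 * s1)
    if kind == "soc":
        return (0.5 * (s2 * s2 - s1 * s1) + (2.0 / 3.0) * (s2**3 - s1**3)) / 3.0
    raise ValueError("sky kind must be 'uoc' or 'soc'")


def _diffuse_patches(n_bands: int, total_patches: int, kind: str):
    edges = np.linspace(0.0, 0.5 * math.pi, n_bands + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    raw = np.cos(mids)
    counts = np.maximum(1, np.floor(raw / raw.sum() * total_patches).astype(int))
    # largest-remainder top-up to the requested patch total
    while counts.sum() < total_patches:
        frac = raw / raw.sum() * total_patches - counts
        counts[int(np.argmax(frac))] += 1
    dirs, wts = [], []
    for b in range(n_bands):
        bw = _diffuse_band_weight(edges[b], edges[b + 1], kind)
        e_mid = mids[b]
        for a in range(counts[b]):
            phi = 2.0 * math.pi * (a + 0.5) / counts[b]
            dirs.append([
                -math.cos(e_mid) * math.cos(phi),
                -math.cos(e_mid) * math.sin(phi),
                -math.sin(e_mid),
            ])
            wts.append(bw / counts[b])
    dirs = np.asarray(dirs)
    wts = np.asarray(wts)
    return dirs, wts / wts.sum()


def _solar_path(latitude: float, day_of_year: int, step_h: float = 0.5):
    """Daylight sun directions and horizontal-irradiance weights."""
    phi = math.radians(latitude)
    dec = math.radians(solar_declination(day_of_year))
    dirs, wts = [], []
    t = 0.0
    while t <= 24.0:
        H = math.radians(15.0 * (t - 12.0))
        sinh = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(H)
        if sinh > 1e-6:
            h = math.asin(min(1.0, sinh))
            cosA = (math.sin(dec) - sinh * math.sin(phi)) / (math.cos(h) * math.cos(phi))
            A = math.acos(min(1.0, max(-1.0, cosA)))  # from north
            if H > 0:
                A = 2.0 * math.pi - A
            sun = np.array([
                math.cos(h) * math.sin(A),  # x = east
                math.cos(h) * math.cos(A),  # y = north
                sinh,
            ])
            dirs.append(-sun)
            wts.append(sinh)
        t += step_h
    if not dirs:
        return np.zeros((0, 3)), np.zeros(0)
    dirs = np.asarray(dirs)
    wts = np.asarray(wts)
    return dirs, wts / wts.sum()


def build_sky(latitude: float, longitude: float = 0.0, day_of_year: int = 172,
              n_bands: int = 6, n_patches: int = 46,
              diffuse_fraction: float = 0.5, kind: str = "soc") -> SkyDome:
    """Site/date-calibrated sky dome (46-patch ring layout by default).

    ``diffuse_fraction`` splits the daily PAR between the diffuse dome
    and the direct solar path sampled at half-hour steps (weights follow
    sin of solar elevation). ``kind`` selects the diffuse radiance
    standard: 'soc' (standard overcast) or 'uoc' (uniform).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year must lie in [1, 366]")
    if not 0.0 <= diffuse_fraction <= 1.0:
        raise ValueError("diffuse_fraction must lie in [0, 1]")
    parts_d, parts_w = [], []
    if diffuse_fraction > 0:
        d, w = _diffuse_patches(n_bands, n_patches, kind)
        parts_d.append(d)
        parts_w.append(w * diffuse_fraction)
    if diffuse_fraction < 1:
        d, w = _solar_path(latitude, day_of_year)
        if len(d) == 0:
            raise ValueError("sun never rises on this date/latitude; "
                             "use diffuse_fraction=1")
        parts_d.append(d)
        parts_w.append(w * (1.0 - diffuse_fraction))
    dirs = np.concatenate(parts_d, axis=0)
    wts = np.concatenate(parts_w)
    return SkyDome(directions=dirs, weights=wts / wts.sum(),
                   latitude=latitude, longitude=longitude,
                   day_of_year=day_of_year, diffuse_fraction=diffuse_fraction)


@dataclass
class AbsorptionMap:
    """Per-surface absorbed radiation and scene-level energy budget.

    Fluxes are J d^-1; ``per_surface_absorbed`` is J m^-2 d^-1 per
    leaflet. ``transmittance`` is Q_T/Q_0: flux density reaching the
    ground over flux density incident above the canopy (NaN without a
    ground surface). ``residual`` is energy terminated at the scatter
    depth limit. incident = leaf + ground + escaped + residual exactly.
    """

    per_surface_absorbed: np.ndarray
    surface_area: np.ndarray
    leaf_absorbed: float
    ground_absorbed: float
    escaped: float
    residual: float
    incident: float
    incident_ground: float
    transmittance: float
    n_rays: int

    @property
    def interception(self) -> float:
        """Fraction of emitted flux absorbed by foliage."""
        return self.leaf_absorbed / self.incident

    def energy_residual(self) -> float:
        """Relative closure error of the energy budget (should be ~1e-16)."""
        total = self.leaf_absorbed + self.ground_absorbed + self.escaped + self.residual
        return abs(self.incident - total) / self.incident


def trace(mesh: Mesh, sky: SkyDome, optics: OpticalProps | None = None,
          n_rays: int = 100_000, max_depth: int = 10, seed: int = 0,
          daily_par_mj: float = 1.0, emission_margin: float | None = None) -> AbsorptionMap:
    """Trace the sky over a canopy mesh and return the absorption map.

    ``daily_par_mj`` is the incident PAR above the canopy
    (MJ m^-2 d^-1); per-surface fluxes scale linearly with it. With a
    ground surface present, the default emission margin is 1 m beyond
    the ground rectangle (0 without ground).
    """
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    optics = optics or OpticalProps()
    q0 = daily_par_mj * MJ  # J m^-2 d^-1

    has_ground = bool(np.any(mesh.is_ground))
    if mesh.n_triangles == 0:
        return AbsorptionMap(
            per_surface_absorbed=np.zeros(0), surface_area=np.zeros(0),
            leaf_absorbed=0.0, ground_absorbed=0.0, escaped=q0, residual=0.0,
            incident=q0, incident_ground=float("nan"), transmittance=float("nan"),
            n_rays=n_rays)

    tris = mesh.triangles
    if has_ground:
        g = tris[mesh.is_ground].reshape(-1, 3)
        mx0, mx1 = float(g[:, 0].min()), float(g[:, 0].max())
        my0, my1 = float(g[:, 1].min()), float(g[:, 1].max())
    else:
        mx0, mx1 = float(tris[..., 0].min()), float(tris[..., 0].max())
        my0, my1 = float(tris[..., 1].min()), float(tris[..., 1].max())
    z_top = float(tris[..., 2].max()) + 0.02
    if emission_margin is None:
        # constant margin keeps the emission area (and thus interception
        # fractions) comparable across canopies of different heights
        emission_margin = 1.0 if has_ground else 0.0
    ex0, ex1 = mx0 - emission_margin, mx1 + emission_margin
    ey0, ey1 = my0 - emission_margin, my1 + emission_margin
    a_emit = (ex1 - ex0) * (ey1 - ey0)
    a_ground = (mx1 - mx0) * (my1 - my0) if has_ground else float("nan")

    # stratified ray allocation over dome directions (largest remainder)
    ideal = sky.weights * n_rays
    counts = np.floor(ideal).astype(np.int64)
    short = n_rays - int(counts.sum())
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1

    v0 = np.ascontiguousarray(tris[:, 0])
    e1 = np.ascontiguousarray(tris[:, 1] - tris[:, 0])
    e2 = np.ascontiguousarray(tris[:, 2] - tris[:, 0])
    nrm = np.cross(e1, e2)
    nrm = np.ascontiguousarray(nrm / np.linalg.norm(nrm, axis=1)[:, None])
    br = mesh.block_ranges
    bmin = np.empty((len(br), 3))
    bmax = np.empty((len(br), 3))
    for i, (a, b) in enumerate(br):
        block = tris[a:b].reshape(-1, 3)
        bmin[i] = block.min(axis=0) - 1e-9
        bmax[i] = block.max(axis=0) + 1e-9
    gb = mesh.group_blocks
    gmin = np.empty((len(gb), 3))
    gmax = np.empty((len(gb), 3))
    for i, (a, b) in enumerate(gb):
        if a == b:  # plant with no meshed leaves yet
            gmin[i], gmax[i] = 1.0, -1.0  # empty box: never hit
        else:
            gmin[i] = bmin[a:b].min(axis=0)
            gmax[i] = bmax[a:b].max(axis=0)

    n_surfaces = int(mesh.surface_id.max()) + 1
    absorbed, ground_down, escaped, residual = trace_kernel(
        v0, e1, e2, nrm, mesh.surface_id, mesh.is_ground,
        br, bmin, bmax, gb, gmin, gmax,
        np.ascontiguousarray(sky.directions), counts,
        ex0, ex1, ey0, ey1, z_top,
        optics.adaxial_reflect, optics.adaxial_transmit,
        optics.abaxial_reflect, optics.abaxial_transmit,
        optics.ground_reflect, optics.ground_transmit,
        max_depth, seed, n_surfaces)

    ray_energy = q0 * a_emit / n_rays  # J d^-1 per ray
    n_leaf = mesh.n_leaf_surfaces
    leaf_counts = absorbed[:n_leaf]
    per_surface = np.zeros(n_leaf)
    nz = mesh.surface_area[:n_leaf] > 0
    per_surface[nz] = leaf_counts[nz] * ray_energy / mesh.surface_area[:n_leaf][nz]
    ground_absorbed = float(absorbed[n_leaf:].sum()) * ray_energy if has_ground else 0.0
    transmittance = (ground_down * ray_energy / a_ground) / q0 if has_ground else float("nan")
    return AbsorptionMap(
        per_surface_absorbed=per_surface,
        surface_area=mesh.surface_area[:n_leaf].copy(),
        leaf_absorbed=float(leaf_counts.sum()) * ray_energy,
        ground_absorbed=ground_absorbed,
        escaped=float(escaped) * ray_energy,
        residual=float(residual) * ray_energy,
        incident=n_rays * ray_energy,
        incident_ground=q0 * a_ground if has_ground else float("nan"),
        transmittance=float(transmittance),
        n_rays=n_rays)


def canopy_transmittance(absorption: AbsorptionMap) -> float:
    """Q_T/Q_0 of a traced scene; requires positive incident flux."""
    if not absorption.incident > 0:
        raise ValueError("transmittance undefined: zero incident flux")
    return absorption.transmittance


def simple_scene(rects, ground_rect=None) -> Mesh:
    """Build a Mesh of horizontal rectangular 'leaves' for controlled scenes.

    ``rects``: iterable of (x0, x1, y0, y1, z) horizontal rectangles,
    each one surface (two triangles, geometric normal = +z = adaxial).
    ``ground_rect``: optional (x0, x1, y0, y1) reflective ground at z=0.
    Used for analytic oracles (single leaf, layered slabs, turbid-medium
    style scenes); every rectangle is its own pruning group.
    """
    tri_list, areas, ranges = [], [], []
    n = 0
    for (x0, x1, y0, y1, z) in rects:
        tri_list.append([[x0, y0, z], [x1, y0, z], [x1, y1, z]])
        tri_list.append([[x0, y0, z], [x1, y1, z], [x0, y1, z]])
        areas.append((x1 - x0) * (y1 - y0))
        ranges.append((n, n + 2))
        n += 2
    n_leaf = len(areas)
    is_ground = [False] * n
    surface_id = list(np.repeat(np.arange(n_leaf), 2))
    if ground_rect is not None:
        x0, x1, y0, y1 = ground_rect
        tri_list.append([[x0, y0, 0.0], [x1, y0, 0.0], [x1, y1, 0.0]])
        tri_list.append([[x0, y0, 0.0], [x1, y1, 0.0], [x0, y1, 0.0]])
        areas.append((x1 - x0) * (y1 - y0))
        surface_id += [n_leaf, n_leaf]
        is_ground += [True, True]
        ranges.append((n, n + 2))
        n += 2
    ranges = np.asarray(ranges, dtype=np.int64).reshape(-1, 2)
    return Mesh(
        triangles=np.asarray(tri_list, dtype=np.float64),
        surface_id=np.asarray(surface_id, dtype=np.int64),
        is_ground=np.asarray(is_ground, dtype=bool),
        surface_area=np.asarray(areas, dtype=float),
        n_leaf_surfaces=n_leaf,
        block_ranges=ranges,
        group_blocks=np.stack([np.arange(len(ranges)),
                               np.arange(1, len(ranges) + 1)], axis=1),
    )
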