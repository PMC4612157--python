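"""Numba kernel for Monte Carlo path tracing over a triangle soup.

Each ray carries unit energy and is traced until it is absorbed,
escapes the scene, or exceeds the scatter-depth limit (counted as
residual), so the energy bookkeeping is exact by construction.
Scattering is stochastic (reflect / transmit / absorb sampled from the
side-specific coefficients) and bi-Lambertian (cosine-weighted about
the surface normal on the appropriate side).

Per-ray randomness comes from a splitmix64/xorshift64* counter scheme
seeded by (seed, ray index), so results are bit-reproducible and
independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-9
_OFFSET = 1e-7


@njit(cache=False, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=False, inline="always")
def _next_u01(state):
    """xorshift64* step; returns (new_state, uniform in [0,1))."""
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    r = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, (r >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def _cosine_dir(ax, ay, az, u1, u2):
    """Cosine-weighted direction in the hemisphere around axis (ax,ay,az)."""
    # orthonormal frame around the axis
    if abs(az) < 0.999:
        tx, ty, tz = ay, -ax, 0.0  # cross(axis, z)
    else:
        tx, ty, tz = 0.0, az, -ay  # cross(axis, x)
    tn = (tx * tx + ty * ty + tz * tz) ** 0.5
    tx, ty, tz = tx / tn, ty / tn, tz / tn
    bx = ay * tz - az * ty
    by = az * tx - ax * tz
    bz = ax * ty - ay * tx
    r = u1 ** 0.5
    phi = 6.283185307179586 * u2
    xl = r * np.cos(phi)
    yl = r * np.sin(phi)
    zl = (1.0 - u1) ** 0.5
    dx = xl * tx + yl * bx + zl * ax
    dy = xl * ty + yl * by + zl * ay
    dz = xl * tz + yl * bz + zl * az
    return dx, dy, dz


@njit(cache=False, fastmath=True, error_model="numpy", inline="always")
def _slab_hit(bmin, bmax, i, ox, oy, oz, ix, iy, iz, t_hi):
    """Ray-AABB slab test with precomputed inverse direction components."""
    t0 = _EPS
    t1 = t_hi
    ta = (bmin[i, 0] - ox) * ix
    tb = (bmax[i, 0] - ox) * ix
    if ta > tb:
        ta, tb = tb, ta
    if ta > t0:
        t0 = ta
    if tb < t1:
        t1 = tb
    if t0 > t1:
        return False
    ta = (bmin[i, 1] - oy) * iy
    tb = (bmax[i, 1] - oy) * iy
    if ta > tb:
        ta, tb = tb, ta
    if ta > t0:
        t0 = ta
    if tb < t1:
        t1 = tb
    if t0 > t1:
        return False
    ta = (bmin[i, 2] - oz) * iz
    tb = (bmax[i, 2] - oz) * iz
    if ta > tb:
        ta, tb = tb, ta
    if ta > t0:
        t0 = ta
    if tb < t1:
        t1 = tb
    return t0 <= t1


@njit(cache=False, fastmath=True, error_model="numpy")
def trace_kernel(v0, e1, e2, nrm, surf_id, ground_tri,
                 block_ranges, bmin, bmax, group_blocks, gmin, gmax,
                 dirs, dir_counts, ex0, ex1, ey0, ey1, ez,
                 rho_ad, tau_ad, rho_ab, tau_ab, rho_g, tau_g,
                 max_depth, seed, n_surfaces):
    absorbed = np.zeros(n_surfaces)
    ground_down = 0.0
    escaped = 0.0
    residual = 0.0
    n_groups = group_blocks.shape[0]
    ray_id = 0
    for j in range(dirs.shape[0]):
        for _ in range(dir_counts[j]):
            state = _splitmix64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                                + np.uint64(ray_id))
            if state == np.uint64(0):
                state = np.uint64(1)
            ray_id += 1
            state, u1 = _next_u01(state)
            state, u2 = _next_u01(state)
            ox = ex0 + u1 * (ex1 - ex0)
            oy = ey0 + u2 * (ey1 - ey0)
            oz = ez
            dx, dy, dz = dirs[j, 0], dirs[j, 1], dirs[j, 2]
            alive = True
            depth = 0
            while alive:
                # nearest hit: plant AABB -> leaf AABB -> triangles
                t_best = 1.0e30
                hit = -1
                ix = 1.0 / dx
                iy = 1.0 / dy
                iz = 1.0 / dz
                for g in range(n_groups):
                    if not _slab_hit(gmin, gmax, g, ox, oy, oz, ix, iy, iz, t_best):
                        continue
                    for blk in range(group_blocks[g, 0], group_blocks[g, 1]):
                        if not _slab_hit(bmin, bmax, blk, ox, oy, oz, ix, iy, iz, t_best):
                            continue
                        for k in range(block_ranges[blk, 0], block_ranges[blk, 1]):
                            # Moller-Trumbore
                            px = dy * e2[k, 2] - dz * e2[k, 1]
                            py = dz * e2[k, 0] - dx * e2[k, 2]
                            pz = dx * e2[k, 1] - dy * e2[k, 0]
                            det = e1[k, 0] * px + e1[k, 1] * py + e1[k, 2] * pz
                            if abs(det) < 1.0e-14:
                                continue
                            inv = 1.0 / det
                            sx = ox - v0[k, 0]
                            sy = oy - v0[k, 1]
                            sz = oz - v0[k, 2]
                            u = (sx * px + sy * py + sz * pz) * inv
                            if u < 0.0 or u > 1.0:
                                continue
                            qx = sy * e1[k, 2] - sz * e1[k, 1]
                            qy = sz * e1[k, 0] - sx * e1[k, 2]
                            qz = sx * e1[k, 1] - sy * e1[k, 0]
                            v = (dx * qx + dy * qy + dz * qz) * inv
                            if v < 0.0 or u + v > 1.0:
                                continue
                            t = (e2[k, 0] * qx + e2[k, 1] * qy + e2[k, 2] * qz) * inv
                            if _EPS < t < t_best:
                                t_best = t
                                hit = k
                if hit < 0:
                    escaped += 1.0
                    break
                ox += t_best * dx
                oy += t_best * dy
                oz += t_best * dz
                s = surf_id[hit]
                if ground_tri[hit]:
                    if dz < 0.0:
                        ground_down += 1.0
                        state, u = _next_u01(state)
                        if u < rho_g:
                            if depth >= max_depth:
                                residual += 1.0
                                break
                            depth += 1
                            state, r1 = _next_u01(state)
                            state, r2 = _next_u01(state)
                            dx, dy, dz = _cosine_dir(0.0, 0.0, 1.0, r1, r2)
                            oz += _OFFSET
                        elif u < rho_g + tau_g:
                            oz -= _OFFSET  # pass through
                        else:
                            absorbed[s] += 1.0
                            break
                    else:
                        # hit from below: treat as absorbed by the soil
                        absorbed[s] += 1.0
                        break
                else:
                    ddn = dx * nrm[hit, 0] + dy * nrm[hit, 1] + dz * nrm[hit, 2]
                    front = ddn < 0.0  # adaxial side faces the geometric normal
                    if front:
                        rho, tau = rho_ad, tau_ad
                    else:
                        rho, tau = rho_ab, tau_ab
                    state, u = _next_u01(state)
                    if u < rho + tau:
                        if depth >= max_depth:
                            residual += 1.0
                            break
                        depth += 1
                        if u < rho:
                            side = 1.0 if front else -1.0  # back out the incidence side
                        else:
                            side = -1.0 if front else 1.0  # through to the other side
                        axx = side * nrm[hit, 0]
                        axy = side * nrm[hit, 1]
                        axz = side * nrm[hit, 2]
                        state, r1 = _next_u01(state)
                        state, r2 = _next_u01(state)
                        dx, dy, dz = _cosine_dir(axx, axy, axz, r1, r2)
                        ox += _OFFSET * axx
                        oy += _OFFSET * axy
                        oz += _OFFSET * axz
                    else:
                        absorbed[s] += 1.0
                        break
    return absorbed, ground_down, escaped, residual
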