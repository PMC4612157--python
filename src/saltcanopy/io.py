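"""File formats and run configuration.

Everything the pipeline writes is an inspectable text artifact: CSV for
tables (climate, harvests, trajectories, k tables, effect and
sensitivity tables), JSON for fits and run reports, Wavefront OBJ for
canopy meshes, YAML for run configurations. Configurations round-trip
load -> save -> load identically and carry a provenance block (package
version, timestamp, content hash of the configuration itself).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import AllometryFit
from .architecture import GrowthParams, Mesh
from .core import ClimateDay, climate_to_frame, frame_to_climate
from .light import OpticalProps
from .production import LUEFunction

__all__ = [
    "write_climate_csv", "read_climate_csv",
    "write_mesh_obj", "write_fits_json", "read_fits_json",
    "default_config", "config_hash", "save_config", "load_config",
    "provenance",
]


def write_climate_csv(days: list[ClimateDay], path) -> None:
    # %.17g round-trips doubles exactly
    climate_to_frame(days).to_csv(path, index=False, float_format="%.17g")


def read_climate_csv(path) -> list[ClimateDay]:
    return frame_to_climate(pd.read_csv(path, float_precision="round_trip"))


def write_mesh_obj(mesh: Mesh, path) -> None:
    """Wavefront OBJ with material groups (leaf adaxial faces + ground).

    Triangles are written with their stored winding; the geometric
    normal of each leaf triangle is its adaxial side.
    """
    lines = ["# saltcanopy canopy mesh", "o canopy"]
    tris = mesh.triangles
    for v in tris.reshape(-1, 3):
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    lines.append("g leaves")
    lines.append("usemtl adaxial")
    for i in range(mesh.n_triangles):
        if mesh.is_ground[i]:
            continue
        b = 3 * i
        lines.append(f"f {b + 1} {b + 2} {b + 3}")
    if np.any(mesh.is_ground):
        lines.append("g ground")
        lines.append("usemtl ground")
        for i in np.nonzero(mesh.is_ground)[0]:
            b = 3 * int(i)
            lines.append(f"f {b + 1} {b + 2} {b + 3}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fits_json(fits: dict, path) -> None:
    payload = {
        "/".join(map(str, key)): {
            "p": f.p, "q": f.q, "r2": f.r2, "p_value": f.p_value,
            "n": f.n, "p_se": f.p_se, "q_se": f.q_se,
        }
        for key, f in fits.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fits_json(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {
        tuple(key.split("/")): AllometryFit(group=tuple(key.split("/")), **val)
        for key, val in raw.items()
    }


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Full parameter set of a pipeline run, as a plain document."""
    return {
        "growth": dataclasses.asdict(GrowthParams()),
        "optics": dataclasses.asdict(OpticalProps()),
        "lue": dataclasses.asdict(LUEFunction()),
        "sky": {"latitude": 52.38, "longitude": 9.62, "doy_start": 90,
                "diffuse_fraction": 0.5},
        "simulation": {"n_days": 80, "n_rays": 5000, "max_depth": 10,
                       "mu": 0.87, "w_p0": 0.25, "seed": 0},
        "scenario": {"regime": "LT", "salinity": [0, 40, 60, 80],
                     "salinity_start": 21},
    }


def config_hash(config: dict) -> str:
    doc = {k: v for k, v in config.items() if k != "provenance"}
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def provenance(config: dict) -> dict:
    return {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config_hash": config_hash(config),
    }


def save_config(config: dict, path) -> None:
    doc = {k: v for k, v in config.items() if k != "provenance"}
    doc["provenance"] = provenance(config)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
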