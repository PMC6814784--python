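"""File formats: config (YAML), tables (CSV), particle fields (legacy VTK),
checkpoints (HDF5), and run logging."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import StabilizationParams, WallModel
from .geometry import ParticleSystem, WallGeometry, build_wall
from .materials import MaterialParams

log = logging.getLogger("aortasph")


# -- configuration ----------------------------------------------------------


def load_config(path):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def parse_config(raw: dict):
    geom = WallGeometry(**raw.get("geometry", {}))
    params = MaterialParams.from_dict(raw.get("materials", {}))
    stab = StabilizationParams(**raw.get("stabilization", {}))
    return geom, params, stab


def config_dict(geom: WallGeometry, params: MaterialParams, stab: StabilizationParams) -> dict:
    return {
        "geometry": dataclasses.asdict(geom),
        "materials": dataclasses.asdict(params),
        "stabilization": dataclasses.asdict(stab),
    }


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


# -- tables -----------------------------------------------------------------


def write_table(df: pd.DataFrame, path, cfg: dict | None = None):
    """CSV with '#'-prefixed header metadata (config hash, timestamp)."""
    with open(path, "w") as fh:
        fh.write(f"# aortasph table written {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        if cfg is not None:
            fh.write(f"# config_hash {config_hash(cfg)}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def particle_table(system: ParticleSystem, record=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "X": system.X[:, 0],
            "Y": system.X[:, 1],
            "R": system.R,
            "theta_deg": np.rad2deg(system.theta),
            "volume": system.V,
            "group": system.group,
            "lamella": system.lamella,
            "band": system.band,
            "ruptured": system.materials.ruptured.astype(int),
        }
    )
    if record is not None:
        df["x"] = record.x[:, 0]
        df["y"] = record.x[:, 1]
        df["sigma_tt_kpa"] = record.sigma_tt
        df["sigma_rr_kpa"] = record.sigma_rr
        df["sigma_zz_kpa"] = record.sigma_zz
    return df


# -- VTK --------------------------------------------------------------------


def write_particles_vtk(path, positions, point_data: dict | None = None):
    """Legacy ASCII VTK polydata point cloud with named point-data arrays."""
    x = np.asarray(positions, dtype=float)
    n = x.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\naortasph particles\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in x:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} 0\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                a = np.asarray(arr)
                if a.shape != (n,):
                    raise ValueError(f"point data {name!r} must be scalar per particle")
                kind = "int" if np.issubdtype(a.dtype, np.integer) else "double"
                fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                for v in a:
                    fh.write(f"{v:.9g}\n" if kind == "double" else f"{int(v)}\n")


def read_particles_vtk(path):
    """Minimal reader for files written by write_particles_vtk (round-trip)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index(next(l for l in lines if l.startswith("POINTS")))
    n = int(lines[i].split()[1])
    pts = np.array([[float(v) for v in lines[i + 1 + k].split()] for k in range(n)])
    data = {}
    for j, l in enumerate(lines):
        if l.startswith("SCALARS"):
            name = l.split()[1]
            vals = [float(v) for v in lines[j + 2 : j + 2 + n]]
            data[name] = np.array(vals)
    return pts[:, :2], data


# -- checkpoints ------------------------------------------------------------

_STATE_ARRAYS = ("mu", "lam", "phib", "contractile", "is_gag", "p_swell", "ruptured")


def save_checkpoint(path, model: WallModel):
    """Full particle state (positions, velocities, material flags, severed
    pairs) as an HDF5 container; bit-exact round trip."""
    with h5py.File(path, "w") as fh:
        fh.attrs["tone_on"] = model.tone_on
        fh.attrs["rim_scale"] = model.rim_scale
        fh.attrs["lambda_z"] = model.lambda_z
        fh.create_dataset("x", data=model.x)
        fh.create_dataset("v", data=model.v)
        fh.create_dataset("edge_active", data=model.table.active)
        g = fh.create_group("materials")
        for name in _STATE_ARRAYS:
            g.create_dataset(name, data=getattr(model.mat, name))
        tips = np.asarray(getattr(model, "damage_tips", []), dtype=float).reshape(-1, 2)
        fh.create_dataset("damage_tips", data=tips)


def load_checkpoint(path, model: WallModel):
    """Restore a checkpoint into a model built from the same config."""
    with h5py.File(path, "r") as fh:
        model.tone_on = bool(fh.attrs["tone_on"])
        model.rim_scale = float(fh.attrs["rim_scale"])
        model.lambda_z = float(fh.attrs["lambda_z"])
        model.x = fh["x"][...]
        model.v = fh["v"][...]
        active = fh["edge_active"][...]
        if active.shape != model.table.active.shape:
            raise ValueError("checkpoint does not match this lattice")
        model.table.active = active.astype(bool)
        for name in _STATE_ARRAYS:
            arr = fh["materials"][name][...]
            getattr(model.mat, name)[...] = arr
        tips = fh["damage_tips"][...]
        model.damage_tips = [tuple(t) for t in tips]
    model.table.compute_corrections()
    return model


# -- logging ----------------------------------------------------------------


def setup_logging(path=None, level=logging.INFO):
    handlers = [logging.StreamHandler()]
    if path is not None:
        handlers.append(logging.FileHandler(path))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    return log
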