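"""Snapshots and model configuration files.

Field snapshots go to legacy ASCII VTK structured-points files or HDF5
arrays (C-order, cell ordering lexicographic with x fastest, as documented
in :mod:`hybridrd.geometry`); particle snapshots go to CSV with columns
(id, species, state, x, y, z, t).  Model configurations round-trip through
plain dictionaries / YAML.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import (EnsembleResult, FieldCoupling, FieldSpec, HybridModel,
                     MembraneCoupling, ParticleSpec)
from .geometry import ParticleSet, SpatialGrid, SurfaceMesh
from .particles import MobilityRule, RateExpr, TransitionRule


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def write_vtk_structured_points(path, grid: SpatialGrid,
                                fields: Dict[str, np.ndarray]) -> None:
    """Legacy VTK structured-points file with cell data."""
    nx, ny, nz = (int(s) for s in grid.shape)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhybridrd field snapshot\n"
                 "ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {grid.lo[0]} {grid.lo[1]} {grid.lo[2]}\n")
        fh.write(f"SPACING {grid.spacing[0]} {grid.spacing[1]} "
                 f"{grid.spacing[2]}\n")
        fh.write(f"CELL_DATA {grid.n_cells}\n")
        for name, vals in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(vals).reshape(-1, 1), fmt="%.10g")


def write_fields_h5(path, grid: SpatialGrid,
                    fields: Dict[str, np.ndarray], t: float = 0.0) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["t"] = t
        f.create_dataset("grid/lo", data=grid.lo)
        f.create_dataset("grid/hi", data=grid.hi)
        f.create_dataset("grid/spacing", data=grid.spacing)
        f.create_dataset("grid/shape", data=grid.shape)
        for name, vals in fields.items():
            f.create_dataset(f"fields/{name}", data=np.asarray(vals))


def write_particles_csv(path, particles: ParticleSet, t: float,
                        mesh: Optional[SurfaceMesh] = None) -> None:
    pos = particles.cartesian(mesh)
    df = pd.DataFrame({
        "id": np.arange(particles.n),
        "species": particles.species,
        "state": [particles.states[c] for c in particles.state],
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "t": t})
    df.to_csv(path, index=False)


def write_ensemble_h5(path, result: EnsembleResult,
                      meta: Optional[dict] = None) -> None:
    """Ensemble record: /realizations/<key>, /ensemble/mean|var, /meta."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.attrs["n"] = result.n
        f.attrs["base_seed"] = result.base_seed
        f.create_dataset("realization_ids", data=result.realization_ids)
        for key, arr in result.data.items():
            f.create_dataset(f"realizations/{key}", data=arr)
            f.create_dataset(f"ensemble/mean/{key}", data=arr.mean(axis=0))
            f.create_dataset(f"ensemble/var/{key}",
                             data=arr.var(axis=0, ddof=1))
        if meta:
            f.create_dataset("meta/config",
                             data=yaml.safe_dump(meta).encode())


def read_ensemble_h5(path) -> EnsembleResult:
    import h5py
    with h5py.File(path, "r") as f:
        data = {k: f[f"realizations/{k}"][...] for k in f["realizations"]}
        return EnsembleResult(f["times"][...], data, int(f.attrs["n"]),
                              int(f.attrs["base_seed"]),
                              f["realization_ids"][...])


# ---------------------------------------------------------------------------
# model configuration round-trip
# ---------------------------------------------------------------------------

def _rate_to_dict(r: RateExpr) -> dict:
    return {"field": r.field, "coeff": r.coeff, "const": r.const,
            "pulse_amp": r.pulse_amp, "pulse_tau": r.pulse_tau}


def model_to_dict(model: HybridModel) -> dict:
    g = model.grid
    d = {
        "name": model.name,
        "dt": model.dt,
        "duration": model.duration,
        "grid": {"extents": [[float(a), float(b)]
                             for a, b in zip(g.lo, g.hi)],
                 "spacing": [float(s) for s in g.spacing],
                 "mask": None if g.mask is None else
                 g.mask.astype(int).tolist()},
        "surface": None if model.surface is None else {
            "vertices": model.surface.vertices.tolist(),
            "triangles": model.surface.triangles.tolist()},
        "fields": [vars(f).copy() for f in model.fields],
        "species": [],
        "couplings": [vars(c).copy() for c in model.couplings],
        "membrane": None if model.membrane is None
        else vars(model.membrane).copy(),
    }
    for s in model.species:
        entry = {
            "name": s.name, "states": list(s.states), "n": s.n,
            "domain": s.domain,
            "initial_state": (s.initial_state
                              if isinstance(s.initial_state, str)
                              else np.asarray(s.initial_state).tolist()),
            "positions": (s.positions if isinstance(s.positions, str)
                          else np.asarray(s.positions).tolist()),
            "transitions": [{"from": r.from_state, "to": r.to_state,
                             "rate": _rate_to_dict(r.rate)}
                            for r in s.transitions],
            "mobility": dict(s.mobility.diffusivity),
        }
        d["species"].append(entry)
    return d


def model_from_dict(d: dict) -> HybridModel:
    from .geometry import build_box_grid
    grid = build_box_grid(d["grid"]["extents"], d["grid"]["spacing"])
    if d["grid"]["mask"] is not None:
        grid = grid.with_mask(np.asarray(d["grid"]["mask"], bool))
    surface = None
    if d["surface"] is not None:
        surface = SurfaceMesh(np.asarray(d["surface"]["vertices"]),
                              np.asarray(d["surface"]["triangles"]))
    fields = [FieldSpec(**f) for f in d["fields"]]
    species = []
    for s in d["species"]:
        rules = [TransitionRule(r["from"], r["to"], RateExpr(**r["rate"]))
                 for r in s["transitions"]]
        init = s["initial_state"]
        if not isinstance(init, str):
            init = np.asarray(init, dtype=np.int64)
        pos = s["positions"]
        if not isinstance(pos, str):
            pos = np.asarray(pos, float)
        species.append(ParticleSpec(
            name=s["name"], states=tuple(s["states"]), n=s["n"],
            domain=s["domain"], initial_state=init, positions=pos,
            transitions=rules,
            mobility=MobilityRule(dict(s["mobility"]))))
    couplings = [FieldCoupling(**c) for c in d["couplings"]]
    membrane = None if d["membrane"] is None \
        else MembraneCoupling(**d["membrane"])
    return HybridModel(grid=grid, fields=fields, species=species,
                       couplings=couplings, membrane=membrane,
                       surface=surface, dt=d["dt"],
                       duration=d["duration"], name=d["name"])


def save_model_yaml(path, model: HybridModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model_yaml(path) -> HybridModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
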