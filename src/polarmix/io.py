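"""Array-container serialization of trajectories and field maps.

Trajectories are stored as self-describing xarray Datasets with named
dimensions (time, y, x, component) and written as NetCDF (classic format
via the scipy backend, no extra binary dependencies); the resolved
configuration and seed travel in a JSON sidecar written next to the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .fields import FieldState
from .params import ModelParams
from .solver import SimulationConfig, Trajectory
from .spectral import Grid

__all__ = [
    "trajectory_to_dataset",
    "dataset_to_trajectory",
    "save_trajectory",
    "load_trajectory",
]


def trajectory_to_dataset(traj: Trajectory) -> xr.Dataset:
    grid = traj.states[0].grid
    coords = {
        "time": traj.times,
        "y": np.arange(grid.n) * grid.h,
        "x": np.arange(grid.n) * grid.h,
        "component": ["x", "y"],
    }
    phi = np.stack([s.phi for s in traj.states])
    P = np.stack([s.P for s in traj.states])
    p = np.stack([np.moveaxis(s.p, 0, -1) for s in traj.states])
    v = np.stack([np.moveaxis(s.v, 0, -1) for s in traj.states])
    ds = xr.Dataset(
        {
            "phi": (("time", "y", "x"), phi),
            "P": (("time", "y", "x"), P),
            "p": (("time", "y", "x", "component"), p),
            "v": (("time", "y", "x", "component"), v),
        },
        coords=coords,
        attrs={
            "L": grid.length,
            "N": grid.n,
            "seed": traj.seed,
        },
    )
    for key, vals in traj.log.items():
        if key == "t":
            continue
        ds[f"log_{key}"] = ("time", np.asarray(vals))
    return ds


def dataset_to_trajectory(ds: xr.Dataset, config: SimulationConfig | None = None) -> Trajectory:
    grid = Grid(int(ds.attrs["N"]), float(ds.attrs["L"]))
    states = []
    for i, t in enumerate(ds.time.values):
        states.append(
            FieldState(
                grid=grid,
                phi=ds.phi.values[i],
                p=np.moveaxis(ds.p.values[i], -1, 0),
                v=np.moveaxis(ds.v.values[i], -1, 0),
                P=ds.P.values[i],
                t=float(t),
            )
        )
    if config is None:
        config = SimulationConfig(params=ModelParams(), N=grid.n)
    log = {
        key.removeprefix("log_"): ds[key].values
        for key in ds.data_vars
        if key.startswith("log_")
    }
    log["t"] = ds.time.values
    return Trajectory(states=states, config=config, seed=int(ds.attrs.get("seed", 0)), log=log)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    ds = trajectory_to_dataset(traj)
    ds.to_netcdf(path, engine="scipy")
    sidecar = {
        "params": traj.config.params.to_dict(),
        "N": traj.config.N,
        "T_end": traj.config.T_end,
        "save_every": traj.config.save_every,
        "stokes_tol": traj.config.stokes_tol,
        "max_picard_iters": traj.config.max_picard_iters,
        "seed": traj.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    ds = xr.load_dataset(path, engine="scipy")
    config = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        config = SimulationConfig(
            params=ModelParams.from_dict(meta["params"]),
            N=meta["N"],
            T_end=meta["T_end"],
            save_every=meta["save_every"],
            stokes_tol=meta["stokes_tol"],
            max_picard_iters=meta["max_picard_iters"],
        )
    return dataset_to_trajectory(ds, config)
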