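"""Serialization of trajectories and analysis artifacts.

Trajectories go to HDF5 (datasets ``times``, ``x``, ``y``; parameters as
root attributes) or to long-format CSV (``time, unit_index, activity``
plus the inhibitory unit under index -1).  Boolean maps, fixed-point
predictions and sweep results serialize to JSON; stimulus specs
round-trip through YAML (see :meth:`fwta.stimuli.StimulusSpec.to_yaml`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .core import Trajectory
from .params import NetworkParameters, PWLParameters

__all__ = [
    "save_trajectory_hdf5",
    "load_trajectory_hdf5",
    "trajectory_to_csv",
    "save_json",
]

PathLike = Union[str, Path]


def save_trajectory_hdf5(traj: Trajectory, path: PathLike) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("x", data=traj.x)
        fh.create_dataset("y", data=traj.y)
        fh.attrs["stimulus_id"] = traj.stimulus_id
        fh.attrs["params_class"] = type(traj.params).__name__
        for key, val in traj.params.to_dict().items():
            fh.attrs[key] = val


def load_trajectory_hdf5(path: PathLike) -> Trajectory:
    with h5py.File(path, "r") as fh:
        attrs = dict(fh.attrs)
        cls = (PWLParameters if attrs.pop("params_class", "NetworkParameters")
               == "PWLParameters" else NetworkParameters)
        stimulus_id = str(attrs.pop("stimulus_id", ""))
        fields = {f.name for f in dataclasses.fields(cls)}
        params = cls(**{k: (int(v) if k == "n_units" else
                            bool(v) if k == "wraparound" else float(v))
                        for k, v in attrs.items() if k in fields})
        return Trajectory(times=fh["times"][()], x=fh["x"][()], y=fh["y"][()],
                          params=params, stimulus_id=stimulus_id)


def trajectory_to_csv(traj: Trajectory, path: PathLike) -> None:
    """Long format: one row per (time, unit); the inhibitory unit is
    stored under ``unit_index = -1``."""
    n_t, n_u = traj.x.shape
    df = pd.DataFrame({
        "time": np.repeat(traj.times, n_u + 1),
        "unit_index": np.tile(np.concatenate([np.arange(n_u), [-1]]), n_t),
        "activity": np.concatenate(
            [np.column_stack([traj.x, traj.y]).ravel()]),
    })
    df.to_csv(path, index=False)


def save_json(obj, path: PathLike) -> None:
    """Serialize any object exposing ``to_dict`` (or a plain dict)."""
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
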