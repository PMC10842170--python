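"""Recording input/output: HDF5 and flat CSV, plus YAML configuration.

An `EnsembleRecording` round-trips through a single HDF5 group (raster,
trajectory, soma coordinates as datasets; labels as attributes) or through a
long-format CSV with one row per frame for interoperability with
spreadsheet-based workflows.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import ArenaSpec, EnsembleRecording, Trajectory

__all__ = ["save_recording", "load_recording", "recording_to_frame", "load_config"]


def save_recording(path, recording: EnsembleRecording, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("raster", "soma_um", "cell_ids"):
            if name in g:
                del g[name]
        g.create_dataset("raster", data=recording.raster, compression="gzip")
        g.create_dataset("soma_um", data=recording.soma_um)
        g.create_dataset("cell_ids", data=recording.cell_ids)
        if "positions" in g:
            del g["positions"]
        g.create_dataset("positions", data=recording.trajectory.positions)
        g.attrs["dt"] = recording.trajectory.dt
        g.attrs["environment"] = recording.environment
        g.attrs["trial"] = recording.trial
        g.attrs["day"] = recording.day
        g.attrs["week"] = recording.week
        g.attrs["arena_shape"] = recording.arena.shape
        g.attrs["arena_extent"] = recording.arena.extent


def load_recording(path, group: str = "/") -> EnsembleRecording:
    with h5py.File(path, "r") as f:
        g = f[group]
        dt = float(g.attrs["dt"])
        positions = g["positions"][()]
        traj = Trajectory(times=np.arange(len(positions)) * dt, positions=positions, dt=dt)
        arena = ArenaSpec(shape=str(g.attrs["arena_shape"]), extent=float(g.attrs["arena_extent"]))
        return EnsembleRecording(
            raster=g["raster"][()],
            trajectory=traj,
            environment=str(g.attrs["environment"]),
            trial=int(g.attrs["trial"]),
            day=int(g.attrs["day"]),
            week=int(g.attrs["week"]),
            soma_um=g["soma_um"][()],
            arena=arena,
            cell_ids=g["cell_ids"][()],
        )


def recording_to_frame(recording: EnsembleRecording) -> pd.DataFrame:
    """One row per frame: time, position, and per-cell activity columns."""
    cols = {
        "time_s": recording.trajectory.times,
        "x_cm": recording.trajectory.positions[:, 0],
        "y_cm": recording.trajectory.positions[:, 1],
    }
    for row, cid in enumerate(recording.cell_ids):
        cols[f"cell_{cid}"] = recording.raster[row]
    return pd.DataFrame(cols)


def load_config(path) -> dict:
    """Flat key-value configuration (YAML; plain ``key: value`` files parse too)."""
    text = Path(path).read_text()
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError("config must be a mapping of keys to values")
    return out
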