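"""Reading and writing trajectories, configs and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .navigator import FlightRecord
from .segmentation import Segmentation, Trajectory

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_flight_csv",
    "load_config_file",
    "write_segmentation_json",
    "write_plume_snapshot_csv",
]


def read_trajectory_csv(path) -> tuple[Trajectory, np.ndarray | None]:
    """Read a trajectory CSV with columns t, x, y, z and optional mode.

    Returns the Trajectory and the per-sample mode labels (or None when the
    file has no mode column).
    """
    df = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV needs columns {sorted(required)}")
    times = df["t"].to_numpy(dtype=float)
    if times.shape[0] >= 2:
        rate = 1.0 / float(np.median(np.diff(times)))
    else:
        rate = 75.0
    traj = Trajectory(times=times,
                      positions=df[["x", "y", "z"]].to_numpy(dtype=float),
                      sample_rate=rate)
    modes = df["mode"].to_numpy(dtype="<U1") if "mode" in df.columns else None
    return traj, modes


def write_trajectory_csv(path, traj: Trajectory, modes=None) -> None:
    df = pd.DataFrame({"t": traj.times, "x": traj.positions[:, 0],
                       "y": traj.positions[:, 1], "z": traj.positions[:, 2]})
    if modes is not None:
        df["mode"] = np.asarray(modes)
    df.to_csv(path, index=False)


def write_flight_csv(path, flight: FlightRecord) -> None:
    write_trajectory_csv(path, flight.trajectory, flight.true_modes)


def load_config_file(path) -> dict:
    """Load a flat YAML or JSON config mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def write_segmentation_json(path, seg: Segmentation) -> None:
    payload = {
        "k": int(seg.k),
        "breakpoints": [int(b) for b in seg.breakpoints],
        "labels": list(seg.labels),
        "objective": float(seg.objective_value),
        "n_velocity_samples": int(seg.n_velocity_samples),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_plume_snapshot_csv(path, plume, t: float) -> None:
    rows = [{"t": t, "puff_id": i,
             "x": p.centre[0], "y": p.centre[1], "z": p.centre[2],
             "sigma": p.spread, "Q": p.strength}
            for i, p in enumerate(plume.puffs)]
    pd.DataFrame(rows, columns=["t", "puff_id", "x", "y", "z", "sigma", "Q"]).to_csv(
        path, index=False)
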