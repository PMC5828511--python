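"""Trajectory table I/O and experiment configuration files.

Canonical table: one row per timestep with columns
``traj_id, t, x, y, z, vx, vy, vz, odor``; rows for one trajectory are
contiguous and time-sorted.  Stored either as CSV or as HDF5 (one group
per trajectory).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from plumetrack.geometry import GaussianPlume, Trajectory, WindTunnelGeometry

COLUMNS = ["traj_id", "t", "x", "y", "z", "vx", "vy", "vz", "odor"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory table (missing columns, bad time axis, ...)."""


def trajectories_to_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": tr.id,
                    "t": tr.times,
                    "x": tr.positions[:, 0],
                    "y": tr.positions[:, 1],
                    "z": tr.positions[:, 2],
                    "vx": tr.velocities[:, 0],
                    "vy": tr.velocities[:, 1],
                    "vz": tr.velocities[:, 2],
                    "odor": tr.concentrations,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing columns: {missing}")
    out: list[Trajectory] = []
    for tid, grp in df.groupby("traj_id", sort=False):
        t = grp["t"].to_numpy(float)
        if len(t) < 2:
            raise TrajectoryFormatError(f"trajectory {tid!r}: fewer than 2 rows")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise TrajectoryFormatError(f"trajectory {tid!r}: non-monotone time column")
        dt = float(np.median(steps))
        if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise TrajectoryFormatError(f"trajectory {tid!r}: mixed sampling interval")
        out.append(
            Trajectory(
                id=str(tid),
                dt=dt,
                positions=grp[["x", "y", "z"]].to_numpy(float),
                velocities=grp[["vx", "vy", "vz"]].to_numpy(float),
                concentrations=grp["odor"].to_numpy(float),
                takeoff_time=float(t[0]),
            )
        )
    return out


def write_trajectories(
    trajs: Sequence[Trajectory], path: str | Path, format: str | None = None
) -> None:
    """Write trajectories as CSV or HDF5 (inferred from suffix by default)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        trajectories_to_frame(trajs).to_csv(path, index=False)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            for i, tr in enumerate(trajs):
                g = f.create_group(f"traj_{i:06d}")
                g.attrs["traj_id"] = tr.id
                g.attrs["dt"] = tr.dt
                g.attrs["takeoff_time"] = tr.takeoff_time
                g.create_dataset("positions", data=tr.positions)
                g.create_dataset("velocities", data=tr.velocities)
                g.create_dataset("concentrations", data=tr.concentrations)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trajectories(path: str | Path, format: str | None = None) -> list[Trajectory]:
    """Read trajectories from a CSV or HDF5 table.

    An empty file yields an empty list; structural problems raise
    :class:`TrajectoryFormatError` naming the offending trajectory.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return []
        if df.empty and not set(COLUMNS) <= set(df.columns):
            return []
        return frame_to_trajectories(df)
    if fmt == "hdf5":
        import h5py

        out = []
        with h5py.File(path, "r") as f:
            for key in sorted(f.keys()):
                g = f[key]
                out.append(
                    Trajectory(
                        id=str(g.attrs["traj_id"]),
                        dt=float(g.attrs["dt"]),
                        positions=g["positions"][()],
                        velocities=g["velocities"][()],
                        concentrations=g["concentrations"][()],
                        takeoff_time=float(g.attrs["takeoff_time"]),
                    )
                )
        return out
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    return "csv"


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment config into a plain dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def env_from_config(cfg: dict) -> WindTunnelGeometry:
    sec = cfg.get("tunnel", {})
    return WindTunnelGeometry(
        flyable_extent=tuple(sec.get("flyable_extent", (1.3, 0.3, 0.3))),
        wind_speed=float(sec.get("wind_speed", 0.4)),
        end_margin=float(sec.get("end_margin", 0.30)),
    )


def plume_from_config(cfg: dict) -> GaussianPlume:
    sec = cfg.get("plume", {})
    return GaussianPlume(
        centerline=tuple(sec.get("centerline", (0.0, 0.0))),
        sigma0=float(sec.get("sigma0", 0.01)),
        widen_rate=float(sec.get("widen_rate", 0.0)),
        c_max=float(sec.get("c_max", 1.0)),
        detection_threshold=float(sec.get("detection_threshold", 0.1)),
    )
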