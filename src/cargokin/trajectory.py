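"""Trajectory container shared by the tracking, motility and kinetics stages.

A trajectory is the time-ordered path of one tracked object (a peroxisome,
an EB3 comet, a nuclear centroid) in physical units: time in seconds,
positions in micrometres. Intensity is carried along for diagnostics but
never enters a metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "trajectories_to_frame", "trajectories_from_frame"]


@dataclass
class Trajectory:
    """Time-ordered 2-D positions (µm) of one tracked object.

    Parameters
    ----------
    id : int
        Trajectory identifier, unique within a collection.
    t : (n,) array
        Sample times in seconds, strictly increasing.
    x, y : (n,) arrays
        Positions in micrometres.
    intensity : (n,) array, optional
        Per-point intensity (arbitrary counts); zeros if absent.
    """

    id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is None:
            self.intensity = np.zeros_like(self.t)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.intensity)):
            raise ValueError("t, x, y, intensity must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in µm."""
        return np.column_stack([self.x, self.y])

    def restrict(self, t0: float, t1: float) -> "Trajectory | None":
        """Sub-trajectory with t0 <= t < t1, or None if < 2 points remain."""
        m = (self.t >= t0) & (self.t < t1)
        if m.sum() < 2:
            return None
        return Trajectory(self.id, self.t[m], self.x[m], self.y[m], self.intensity[m])


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a long-format table (schema v1)."""
    if not trajs:
        return pd.DataFrame(
            columns=["trajectory_id", "t_s", "x_um", "y_um", "intensity"]
        )
    parts = [
        pd.DataFrame(
            {
                "trajectory_id": tr.id,
                "t_s": tr.t,
                "x_um": tr.x,
                "y_um": tr.y,
                "intensity": tr.intensity,
            }
        )
        for tr in trajs
    ]
    return pd.concat(parts, ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for tid, g in df.groupby("trajectory_id", sort=True):
        g = g.sort_values("t_s")
        out.append(
            Trajectory(
                int(tid),
                g["t_s"].to_numpy(),
                g["x_um"].to_numpy(),
                g["y_um"].to_numpy(),
                g["intensity"].to_numpy() if "intensity" in g else None,
            )
        )
    return out
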