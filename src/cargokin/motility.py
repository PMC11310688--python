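"""Trajectory-level cargo and nucleus metrics.

Displacement measures, the geometric active-cargo filter (radial alignment
within a maximum angle plus a minimum travel distance, with cell-edge
exclusion), radial fluorescence profiles, and organelle-size ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.measure import label, regionprops

from .geometry import CellGeometry
from .trajectory import Trajectory

__all__ = [
    "MotilityParams",
    "RadialProfile",
    "net_displacement",
    "total_travel",
    "radial_alignment_angle",
    "exclude_edge",
    "count_active",
    "radial_profile",
    "area_ratio",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given trajectory."""


@dataclass
class MotilityParams:
    """Active-cargo filter configuration.

    A trajectory counts as actively transported in a time window when its
    net-displacement direction lies within ``theta_max`` degrees of the
    radial axis and its travel in the window exceeds ``d_min`` µm, after
    excluding cargoes within ``edge_margin`` µm of the cell boundary (edge
    movements reflect microtubule dynamics, not transport).
    """

    theta_max: float = 45.0
    d_min: float = 3.0
    window: float = 300.0
    edge_margin: float = 1.0
    travel_measure: str = "total"  # "total" path length or "net" displacement
    angle_mode: str = "net"        # "net" vector or "per_step" majority

    def __post_init__(self) -> None:
        if not 0 < self.theta_max <= 90:
            raise ValueError("theta_max must be in (0, 90]")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.travel_measure not in ("total", "net"):
            raise ValueError("travel_measure must be 'total' or 'net'")
        if self.angle_mode not in ("net", "per_step"):
            raise ValueError("angle_mode must be 'net' or 'per_step'")


@dataclass
class RadialProfile:
    """Summed intensity vs. distance from the cell centre."""

    bin_edges: np.ndarray      # (k+1,) µm
    summed_intensity: np.ndarray  # (k,) counts

    @property
    def total(self) -> float:
        return float(self.summed_intensity.sum())


def net_displacement(traj: Trajectory) -> float:
    """Euclidean distance (µm) between the first and last positions."""
    if len(traj) < 2:
        raise UndefinedMetricError("net displacement needs >= 2 points")
    return float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))


def total_travel(traj: Trajectory) -> float:
    """Summed step lengths (µm); always >= net displacement."""
    if len(traj) < 2:
        raise UndefinedMetricError("total travel needs >= 2 points")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def radial_alignment_angle(traj: Trajectory, geom: CellGeometry) -> float:
    """Acute angle (degrees) between the net displacement and the radial axis.

    The radial axis is the undirected line through the cell centre and the
    trajectory's first point, so inward and outward movements both score
    small angles. Undefined for zero net displacement.
    """
    if net_displacement(traj) == 0:
        raise UndefinedMetricError("alignment angle undefined for zero displacement")
    d = np.array([traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]])
    u = geom.radial_unit(traj.x[0], traj.y[0])
    cosang = abs(float(np.dot(d, u))) / np.linalg.norm(d)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _per_step_alignment(traj: Trajectory, geom: CellGeometry) -> float:
    """Travel-weighted mean per-step angle to the local radial axis."""
    steps = np.diff(traj.positions, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    keep = lens > 0
    if not keep.any():
        raise UndefinedMetricError("no displacement")
    angs = []
    for k in np.nonzero(keep)[0]:
        u = geom.radial_unit(traj.x[k], traj.y[k])
        c = abs(float(np.dot(steps[k], u))) / lens[k]
        angs.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return float(np.average(angs, weights=lens[keep]))


def exclude_edge(
    trajs: list[Trajectory], geom: CellGeometry, margin: float
) -> list[Trajectory]:
    """Drop trajectories whose mean position is within ``margin`` µm of the
    cell boundary."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return list(trajs)
    out = []
    for tr in trajs:
        mx, my = float(tr.x.mean()), float(tr.y.mean())
        if geom.distance_to_boundary(mx, my) > margin:
            out.append(tr)
    return out


def is_active(
    traj: Trajectory, geom: CellGeometry, mp: MotilityParams
) -> bool:
    """Active-transport test for one (window-restricted) trajectory."""
    if len(traj) < 2:
        return False
    travel = total_travel(traj) if mp.travel_measure == "total" else net_displacement(traj)
    if not travel > mp.d_min:
        return False
    try:
        if mp.angle_mode == "net":
            ang = radial_alignment_angle(traj, geom)
        else:
            ang = _per_step_alignment(traj, geom)
    except UndefinedMetricError:
        return False
    return ang <= mp.theta_max


def count_active(
    trajs: list[Trajectory],
    geom: CellGeometry,
    mp: MotilityParams,
    t_total: float,
) -> pd.DataFrame:
    """Count actively transported cargoes per time window.

    Windows of length ``mp.window`` tile [0, t_total]. Per window, each
    trajectory is restricted to that window and counted when it passes the
    geometric filter; the normalized series divides by the count in the
    first window. Returns a table (window, t_start, t_end, n_active,
    normalized).
    """
    n_win = int(np.ceil(t_total / mp.window))
    if n_win < 1:
        raise ValueError("t_total must cover at least one window")
    kept = exclude_edge(trajs, geom, mp.edge_margin)
    rows = []
    for w in range(n_win):
        t0, t1 = w * mp.window, min((w + 1) * mp.window, t_total)
        # right-closed on the final window so the last sample is not lost
        t1_sel = t1 + 1e-9 if w == n_win - 1 else t1
        n = 0
        for tr in kept:
            sub = tr.restrict(t0, t1_sel)
            if sub is not None and is_active(sub, geom, mp):
                n += 1
        rows.append((w, t0, t1, n))
    df = pd.DataFrame(rows, columns=["window", "t_start", "t_end", "n_active"])
    n0 = df["n_active"].iloc[0]
    if n0 == 0:
        raise ValueError("no active cargoes in the first window: normalization undefined")
    df["normalized"] = df["n_active"] / n0
    return df


def radial_profile(
    frame_image: np.ndarray,
    geom: CellGeometry,
    bin_width: float,
    pixel_size: float,
) -> RadialProfile:
    """Sum pixel intensities by distance from the cell centre.

    Pixels inside the boundary polygon are binned by their centre-to-centre
    distance; the per-bin sums conserve the total masked intensity exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    img = np.asarray(frame_image, dtype=float)
    poly_px = geom.boundary[:, ::-1] / pixel_size  # (row, col) vertex order
    mask = polygon2mask(img.shape, poly_px)
    rr, cc = np.nonzero(mask)
    d = np.hypot(
        cc * pixel_size - geom.center[0], rr * pixel_size - geom.center[1]
    )
    d_max = d.max() if len(d) else bin_width
    n_bins = max(1, int(np.ceil(d_max / bin_width)))
    if bin_width > d_max:
        warnings.warn("bin_width exceeds the cell radius: single-bin profile")
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((d / bin_width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=img[rr, cc], minlength=n_bins)
    return RadialProfile(edges, sums)


def area_ratio(
    labeled_image_test: np.ndarray,
    labeled_image_ref: np.ndarray,
    pixel_size: float,
) -> float:
    """Fold change in mean connected-component area (test / reference).

    Inputs may be binary or labeled images; binary images are labeled with
    8-connectivity. Areas are measured in µm² (pixel count × pixel_size²);
    the ratio is dimensionless.
    """
    means = []
    for img in (labeled_image_test, labeled_image_ref):
        arr = np.asarray(img)
        lab = label(arr > 0, connectivity=2)
        props = regionprops(lab)
        if not props:
            raise ValueError("image contains no connected components")
        means.append(np.mean([p.area for p in props]) * pixel_size**2)
    return float(means[0] / means[1])
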