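"""Neuron-specific nucleus–microtubule coupling metrics.

Covers the duration of nuclear rotations beyond a threshold angle, the
forward speed of a photoconverted microtubule patch, the normalized change
of the nucleus–microtubule (NM) distance, and the outward fraction of EB3
comet directions on a radial microtubule array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry
from .simulate import PhotoconvPair
from .trajectory import Trajectory

__all__ = [
    "OrientationSeries",
    "rotation_duration",
    "mt_patch_speed",
    "nm_distance_change",
    "eb3_direction_fraction",
]


@dataclass
class OrientationSeries:
    """Unwrapped nucleus orientation (degrees) over time (s)."""

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.t) != len(self.theta):
            raise ValueError("t and theta must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")


def _monotonic_episodes(theta: np.ndarray, hysteresis: float) -> list[tuple[int, int]]:
    """Maximal monotonic episodes [i0, i1] (sample indices), with reversals
    committed only when the counter-movement from the running extremum
    exceeds ``hysteresis`` degrees."""
    n = len(theta)
    episodes = []
    start = 0
    direction = 0  # 0 unknown, +1 rising, -1 falling
    ext = theta[0]
    ext_i = 0
    for i in range(1, n):
        d = theta[i] - ext
        if direction == 0:
            if abs(d) > hysteresis:
                direction = 1 if d > 0 else -1
                ext, ext_i = theta[i], i
            elif (d > 0 and theta[i] > ext) or (d < 0 and theta[i] < ext):
                pass
        elif direction * (theta[i] - ext) >= 0:
            ext, ext_i = theta[i], i  # continuing the sweep
        elif abs(theta[i] - ext) > hysteresis:
            episodes.append((start, ext_i))  # reversal committed at extremum
            start = ext_i
            direction = -direction
            ext, ext_i = theta[i], i
    episodes.append((start, n - 1))
    return episodes


def rotation_duration(
    o: OrientationSeries, theta_rot: float = 10.0, hysteresis: float = 1.0
) -> float:
    """Total time (s) the nucleus spends in rotations larger than theta_rot.

    The orientation series is decomposed into maximal monotonic episodes
    (a 1° hysteresis suppresses measurement jitter); the durations of all
    episodes whose total angular change exceeds ``theta_rot`` degrees are
    summed. Invariant to adding a constant angle or shifting time.
    """
    if len(o.t) < 2:
        return 0.0
    total = 0.0
    for i0, i1 in _monotonic_episodes(o.theta, hysteresis):
        if abs(o.theta[i1] - o.theta[i0]) > theta_rot:
            total += o.t[i1] - o.t[i0]
    return float(total)


def _series_at(t: np.ndarray, y: np.ndarray, tq: float) -> float:
    if tq < t[0] - 1e-9 or tq > t[-1] + 1e-9:
        raise ValueError(f"time {tq} s outside the recorded series")
    return float(np.interp(tq, t, y))


def mt_patch_speed(p: PhotoconvPair, t0: float, t1: float) -> float:
    """Photoconverted-patch speed (µm/min) from initial and final centroids.

    Computed as |patch(t1) − patch(t0)| / (t1 − t0), converted to µm/min.
    The window conventionally starts >= 3 min and ends <= 6 min after
    photoconversion.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if t0 < p.t0_conv:
        raise ValueError("window starts before photoconversion")
    d = abs(
        _series_at(p.t, p.patch_centroid, t1) - _series_at(p.t, p.patch_centroid, t0)
    )
    return d / (t1 - t0) * 60.0


def nm_distance_change(p: PhotoconvPair, t0: float, t1: float) -> float:
    """Change of the NM distance over [t0, t1], normalized to its initial value.

    D(t) = patch(t) − nucleus_front(t); returns (D(t1) − D(t0)) / D(t0).
    Zero when nucleus and patch move synchronously; positive when the
    nucleus lags behind the advancing microtubules. Invariant to a common
    drift added to both series.
    """
    d0 = _series_at(p.t, p.patch_centroid, t0) - _series_at(p.t, p.nucleus_front, t0)
    if d0 <= 0:
        raise ValueError("initial NM distance must be positive (patch ahead of nucleus)")
    d1 = _series_at(p.t, p.patch_centroid, t1) - _series_at(p.t, p.nucleus_front, t1)
    return (d1 - d0) / d0


def eb3_direction_fraction(
    trajs: list[Trajectory], geom: CellGeometry
) -> tuple[float, np.ndarray]:
    """Fraction of EB3 comets moving toward the cell periphery.

    A comet is outward when the radial component of its net displacement
    (relative to the cell centre, evaluated at its starting point) is
    positive. Comets with zero net displacement are excluded with a
    warning. Returns (outward fraction, per-comet boolean labels).
    """
    labels = []
    for tr in trajs:
        d = np.array([tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]])
        if np.hypot(*d) == 0:
            warnings.warn(f"comet {tr.id} has zero net displacement; excluded")
            continue
        u = geom.radial_unit(tr.x[0], tr.y[0])
        labels.append(float(np.dot(d, u)) > 0)
    if not labels:
        raise ValueError("no classifiable comets")
    labels = np.asarray(labels, dtype=bool)
    return float(labels.mean()), labels
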