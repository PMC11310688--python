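"""Frame-to-frame particle linking with the Hungarian algorithm.

Consecutive frames are linked by the assignment that minimizes the total
squared displacement, with links longer than ``max_step`` forbidden. The
cost matrix is augmented with per-particle "no link" alternatives at cost
max_step², so a particle is left unlinked exactly when that lowers the
total cost; unmatched spots terminate or open trajectories. Link range is
fixed to one frame (no gap closing): a spot that blinks off splits its
trajectory by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Spot
from .trajectory import Trajectory

__all__ = ["LinkParams", "link_spots", "frame_assignment"]

_BIG = 1e12


@dataclass
class LinkParams:
    """Linking configuration: maximum step length (µm) and link range."""

    max_step: float = 7.0
    link_range: int = 1

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.link_range != 1:
            raise ValueError("only link_range = 1 is supported (no gap closing)")


def frame_assignment(
    prev_xy: np.ndarray, next_xy: np.ndarray, max_step: float
) -> list[tuple[int, int]]:
    """Optimal links between two frames.

    Returns (i, j) index pairs linking ``prev_xy[i]`` to ``next_xy[j]`` under
    the minimum-total-squared-displacement criterion with unlink cost
    max_step² per particle and links beyond max_step forbidden.
    """
    n1, n2 = len(prev_xy), len(next_xy)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    b = max_step**2
    cost = np.full((n1 + n2, n2 + n1), _BIG)
    link = np.where(d2 <= b, d2, _BIG)
    cost[:n1, :n2] = link
    cost[:n1, n2:] = np.where(np.eye(n1, dtype=bool), b, _BIG)  # i unlinked
    cost[n1:, :n2] = np.where(np.eye(n2, dtype=bool), b, _BIG)  # j newborn
    cost[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n1 and j < n2 and d2[i, j] <= b
    ]


def link_spots(
    spots_by_frame: dict[int, list[Spot]] | list[list[Spot]],
    lp: LinkParams,
    dt: float = 1.0,
) -> list[Trajectory]:
    """Link per-frame spot lists into trajectories.

    Every input spot belongs to exactly one output trajectory; trajectories
    are ordered and numbered by first appearance (frame, then y, then x of
    the opening spot). ``dt`` converts frame indices to seconds.
    """
    if isinstance(spots_by_frame, dict):
        frames = sorted(spots_by_frame)
        per_frame = [spots_by_frame[f] for f in frames]
    else:
        frames = list(range(len(spots_by_frame)))
        per_frame = list(spots_by_frame)

    chains: list[list[Spot]] = []
    open_idx: list[int] = []  # chain index per spot of previous frame
    prev_frame = None
    prev_spots: list[Spot] = []
    for f, spots in zip(frames, per_frame):
        if prev_frame is not None and f == prev_frame + 1 and prev_spots and spots:
            prev_xy = np.array([[s.x, s.y] for s in prev_spots])
            next_xy = np.array([[s.x, s.y] for s in spots])
            pairs = dict(frame_assignment(prev_xy, next_xy, lp.max_step))
        else:
            pairs = {}
        inv = {j: i for i, j in pairs.items()}
        new_open = []
        for j, s in enumerate(spots):
            if j in inv:
                ci = open_idx[inv[j]]
                chains[ci].append(s)
                new_open.append(ci)
            else:
                chains.append([s])
                new_open.append(len(chains) - 1)
        open_idx = new_open
        prev_frame, prev_spots = f, spots

    chains.sort(key=lambda ch: (ch[0].frame, ch[0].y, ch[0].x))
    trajs = []
    for tid, ch in enumerate(chains):
        trajs.append(
            Trajectory(
                tid,
                np.array([s.frame * dt for s in ch]),
                np.array([s.x for s in ch]),
                np.array([s.y for s in ch]),
                np.array([s.intensity for s in ch]),
            )
        )
    return trajs
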