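"""Stochastic generators for cargo transport, nuclear drift, EB3 comets and
photoconverted microtubule patches.

The cargo model is a three-state continuous-time Markov chain on a single
microtubule axis: a minus-end-directed processive run, a plus-end-directed
processive run, and a pause. Dwell times are exponential (rates in s⁻¹);
state changes always pass through the pause state, which matches transport
that proceeds as short processive runs interspersed by pausing or detaching
rather than instantaneous reversals. Event times are drawn exactly
(Gillespie) and the position is then sampled on the acquisition grid, so
the statistics do not depend on the sampling interval.

Conventions: positive positions/velocities point toward the microtubule
plus end (cell centre → periphery). All lengths µm, times s, rates s⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellGeometry, circular_cell
from .trajectory import Trajectory

__all__ = [
    "MotorModelParams",
    "NuclearTrackParams",
    "CellField",
    "Episode",
    "CargoTrack",
    "PhotoconvPair",
    "EB3Field",
    "simulate_cargo",
    "simulate_nucleus",
    "simulate_eb3",
    "simulate_photoconv_pair",
    "embed_radial",
]

PAUSE, MINUS, PLUS = "pause", "minus", "plus"


@dataclass
class MotorModelParams:
    """Rates and speeds of the minus-run / plus-run / pause cargo model.

    Defaults reproduce bidirectional adaptor-driven transport: ~1 µm/s in
    both directions, a 0.3:0.2 s⁻¹ initiation-rate ratio (so 60% of runs are
    minus-end-directed at stationarity), and 2 µm mean run length. The
    pause↔run rates are illustrative round numbers — they are not fitted
    measurements.

    Attributes
    ----------
    v_minus, v_plus : float
        Run speeds, µm/s (> 0; the minus speed is applied with negative sign).
    sigma_v : float
        Per-sampling-step Gaussian velocity jitter SD, µm/s (truncated at 0
        so a run never reverses sign).
    k_start_minus, k_start_plus : float
        Pause → run initiation rates, s⁻¹.
    k_end_minus, k_end_plus : float
        Run → pause termination rates, s⁻¹. Expected run length in direction
        d is v_d / k_end_d when sigma_v = 0.
    d_pause : float
        Diffusion coefficient during pauses, µm²/s (detachment is modelled as
        a diffusive pause, keeping the ground truth one-dimensional).
    sigma_loc : float
        Localization noise SD added to the observed positions, µm.
    """

    v_minus: float = 1.0
    v_plus: float = 1.0
    sigma_v: float = 0.1
    k_start_minus: float = 0.3
    k_start_plus: float = 0.2
    k_end_minus: float = 0.5
    k_end_plus: float = 0.5
    d_pause: float = 0.005
    sigma_loc: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "v_minus", "v_plus", "sigma_v", "k_start_minus", "k_start_plus",
            "k_end_minus", "k_end_plus", "d_pause", "sigma_loc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def stationary_minus_fraction(self) -> float:
        """Probability that an initiated run is minus-directed."""
        tot = self.k_start_minus + self.k_start_plus
        if tot == 0:
            raise ValueError("no initiation: both start rates are zero")
        return self.k_start_minus / tot


@dataclass
class NuclearTrackParams:
    """Drift-plus-fluctuation model of a migrating nucleus centroid.

    The nucleus advances at ``drift_speed`` µm/s along ``axis`` while
    fluctuating isotropically about that drifting anchor with per-sample
    Gaussian SD ``sigma_step`` µm. The fluctuation does not accumulate —
    the nucleus is tethered by the cytoskeleton, not freely diffusing — so
    the expected net displacement equals drift_speed × duration while the
    per-interval displacements show the frequent backward steps of real
    nuclear migration.
    """

    drift_speed: float = 3.586e-3  # µm/s  (≈ 12.9 µm/h)
    sigma_step: float = 0.5
    dt: float = 30.0
    duration: float = 3600.0
    axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.sigma_step < 0:
            raise ValueError("sigma_step must be >= 0")


@dataclass
class CellField:
    """Radial microtubule array inside a cell outline.

    ``polarity_inverted_fraction`` is the fraction of filaments whose plus
    end points toward the cell centre instead of the periphery.
    """

    geometry: CellGeometry
    polarity_inverted_fraction: float = 0.1
    mt_count: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.polarity_inverted_fraction <= 1.0:
            raise ValueError("polarity_inverted_fraction must be in [0, 1]")


@dataclass
class Episode:
    """One ground-truth state interval of a simulated cargo."""

    state: str          # pause | minus | plus
    t_start: float
    t_end: float
    s_start: float
    s_end: float
    censored: bool = False  # cut short by the observation window

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def length(self) -> float:
        """Unsigned distance covered, µm."""
        return abs(self.s_end - self.s_start)


@dataclass
class CargoTrack:
    """Simulated 1-D cargo trace with its ground truth.

    ``s`` is the observed position series (localization noise included),
    ``s_true`` the noiseless one; ``episodes`` lists every state interval.
    """

    t: np.ndarray
    s: np.ndarray
    s_true: np.ndarray
    episodes: list[Episode]

    def runs(self, include_censored: bool = True) -> list[Episode]:
        out = [e for e in self.episodes if e.state != PAUSE]
        if not include_censored:
            out = [e for e in out if not e.censored]
        return out


@dataclass
class PhotoconvPair:
    """Coupled nucleus-front / photoconverted-MT-patch position series.

    Both series are 1-D positions (µm) along the migration axis on a common
    time base, defined from the photoconversion time ``t0_conv`` onward.
    """

    t: np.ndarray
    nucleus_front: np.ndarray
    patch_centroid: np.ndarray
    t0_conv: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.nucleus_front = np.asarray(self.nucleus_front, dtype=float)
        self.patch_centroid = np.asarray(self.patch_centroid, dtype=float)
        if not (len(self.t) == len(self.nucleus_front) == len(self.patch_centroid)):
            raise ValueError("series must share one time base")


@dataclass
class EB3Field:
    """Simulated EB3 comets with their ground-truth polarity labels."""

    trajectories: list[Trajectory]
    outward_true: np.ndarray  # bool per comet
    field: CellField


# ---------------------------------------------------------------------------
# cargo simulation
# ---------------------------------------------------------------------------

def _gillespie_schedule(p: MotorModelParams, duration: float, rng) -> list[list]:
    """Exact event sequence [(state, t0, t1), ...] covering [0, duration]."""
    sched = []
    t = 0.0
    state = PAUSE
    while t < duration:
        if state == PAUSE:
            rate = p.k_start_minus + p.k_start_plus
        elif state == MINUS:
            rate = p.k_end_minus
        else:
            rate = p.k_end_plus
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_end = min(t + dwell, duration)
        sched.append([state, t, t_end])
        t = t_end
        if t >= duration:
            break
        if state == PAUSE:
            state = MINUS if rng.random() < p.stationary_minus_fraction else PLUS
        else:
            state = PAUSE
    return sched


def simulate_cargo(
    params: MotorModelParams,
    n: int,
    duration: float,
    dt: float,
    seed: int,
) -> list[CargoTrack]:
    """Simulate ``n`` cargoes on the microtubule axis for ``duration`` s.

    Returns one :class:`CargoTrack` per cargo, sampled every ``dt`` s, with
    the exact ground-truth state schedule retained. Cargoes start in the
    pause state. Identical seed and parameters give identical output.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    duration = n_steps * dt  # snap to the sampling grid
    t_grid = np.arange(n_steps + 1) * dt
    tracks = []
    for _ in range(n):
        sched = _gillespie_schedule(params, duration, rng)
        # elementary intervals: schedule events cut by the sampling grid
        cuts = np.unique(np.concatenate([t_grid, [iv[1] for iv in sched]]))
        cuts = cuts[(cuts >= 0) & (cuts <= duration)]
        s_true = np.zeros(n_steps + 1)
        ep_disp = [0.0] * len(sched)
        # jitter drawn once per sampling step while in a run
        step_speed: dict[tuple[int, int], float] = {}
        pos = 0.0
        ei = 0
        for a, b in zip(cuts[:-1], cuts[1:]):
            while sched[ei][2] <= a + 1e-12 and ei < len(sched) - 1:
                ei += 1
            state = sched[ei][0]
            tau = b - a
            if state == PAUSE:
                dx = (
                    rng.normal(0.0, np.sqrt(2.0 * params.d_pause * tau))
                    if params.d_pause > 0
                    else 0.0
                )
            else:
                g = int(a / dt + 1e-9)
                key = (g, ei)
                if key not in step_speed:
                    v0 = params.v_minus if state == MINUS else params.v_plus
                    sp = v0 + rng.normal(0.0, params.sigma_v) if params.sigma_v > 0 else v0
                    step_speed[key] = max(sp, 0.0)
                dx = step_speed[key] * tau * (-1.0 if state == MINUS else 1.0)
            pos += dx
            ep_disp[ei] += dx
            gi = int(b / dt + 0.5)
            if abs(b - gi * dt) < 1e-9 * max(1.0, duration):
                s_true[gi] = pos
        # assemble ground-truth episodes with their positions
        episodes = []
        s0 = 0.0
        for (state, ta, tb), d in zip(sched, ep_disp):
            episodes.append(
                Episode(state, ta, tb, s0, s0 + d, censored=(tb >= duration - 1e-12))
            )
            s0 += d
        s_obs = s_true + (
            rng.normal(0.0, params.sigma_loc, s_true.shape)
            if params.sigma_loc > 0
            else 0.0
        )
        tracks.append(CargoTrack(t_grid.copy(), s_obs, s_true, episodes))
    return tracks


def embed_radial(
    track: CargoTrack,
    geometry: CellGeometry,
    seed: int,
    margin: float = 2.0,
    traj_id: int = 0,
) -> Trajectory:
    """Embed a 1-D cargo trace on a radial axis inside the cell.

    The track is placed on a ray of random angle through the cell centre at a
    starting radius chosen so the whole excursion stays ``margin`` µm away
    from the centre and the boundary. Positive 1-D positions map outward
    (toward the plus ends at the periphery). The noiseless positions are
    embedded — when the result is rendered and re-detected, localization
    noise arises in the imaging, not in the geometry.
    """
    rng = np.random.default_rng(seed)
    r_max = geometry.max_radius()
    lo, hi = track.s_true.min(), track.s_true.max()
    span = hi - lo
    if span > r_max - 2 * margin:
        raise ValueError("track excursion does not fit inside the cell")
    r0 = rng.uniform(margin - lo, r_max - margin - hi)
    ang = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(ang), np.sin(ang)])
    cx, cy = geometry.center
    r = r0 + track.s_true
    return Trajectory(traj_id, track.t, cx + r * u[0], cy + r * u[1])


# ---------------------------------------------------------------------------
# nucleus, EB3, photoconversion
# ---------------------------------------------------------------------------

def simulate_nucleus(p: NuclearTrackParams, n: int, seed: int) -> list[Trajectory]:
    """Simulate ``n`` nuclear-centroid tracks: drift plus tethered jitter.

    Mean net displacement over tracks converges to drift_speed × duration
    (the zero-mean fluctuation cancels in expectation); per-interval
    displacements mix forward and frequent backward steps.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(p.duration / p.dt))
    t = np.arange(n_steps + 1) * p.dt
    axis = np.asarray(p.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    out = []
    for i in range(n):
        jitter = rng.normal(0.0, p.sigma_step, size=(n_steps + 1, 2))
        if p.sigma_step > 0:
            jitter[0] = 0.0  # tracks start at the measured origin
        pos = p.drift_speed * t[:, None] * axis[None, :] + jitter
        out.append(Trajectory(i, t, pos[:, 0], pos[:, 1]))
    return out


def simulate_eb3(
    field: CellField,
    n_comets: int,
    speed: float = 0.3,
    seed: int = 0,
    duration: float = 10.0,
    dt: float = 0.5,
) -> EB3Field:
    """Simulate EB3 comets on a radial microtubule field.

    Each comet travels at constant ``speed`` µm/s along a radial filament,
    outward (toward the periphery) unless its filament has inverted
    polarity, which happens with probability ``polarity_inverted_fraction``.
    Ground-truth direction labels are retained.
    """
    rng = np.random.default_rng(seed)
    geom = field.geometry
    r_max = geom.max_radius()
    t = np.arange(int(round(duration / dt)) + 1) * dt
    travel = speed * duration
    trajs, outward = [], np.zeros(n_comets, dtype=bool)
    cx, cy = geom.center
    for i in range(n_comets):
        inv = rng.random() < field.polarity_inverted_fraction
        outward[i] = not inv
        ang = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(ang), np.sin(ang)])
        # start radius keeps the full excursion inside [0.05R, 0.9R]
        lo, hi = 0.05 * r_max, 0.9 * r_max
        if inv:
            r0 = rng.uniform(lo + travel, hi)
            r = r0 - speed * t
        else:
            r0 = rng.uniform(lo, hi - travel)
            r = r0 + speed * t
        trajs.append(Trajectory(i, t, cx + r * u[0], cy + r * u[1]))
    return EB3Field(trajs, outward, field)


def simulate_photoconv_pair(
    nucleus_drift: float,
    patch_drift: float,
    initial_nm_distance: float,
    sigma_loc: float,
    dt: float,
    duration: float,
    seed: int,
) -> PhotoconvPair:
    """Simulate a nucleus-front / MT-patch pair after photoconversion.

    Both series drift linearly (µm/s) from their initial positions with
    independent Gaussian localization noise of SD ``sigma_loc`` µm at each
    sample. The patch starts ``initial_nm_distance`` µm ahead of the nucleus
    front.
    """
    if initial_nm_distance <= 0:
        raise ValueError("initial_nm_distance must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration / dt)) + 1) * dt
    noise = lambda: rng.normal(0.0, sigma_loc, t.shape) if sigma_loc > 0 else 0.0
    nucleus = nucleus_drift * t + noise()
    patch = initial_nm_distance + patch_drift * t + noise()
    return PhotoconvPair(t, nucleus, patch, t0_conv=0.0)
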