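"""End-to-end analysis pipeline: detect → track → motility → kinetics.

A single YAML-backed configuration (one top-level seed, physical units
µm/s) drives every stage; all output files record the configuration hash,
and the same config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ckio
from .detect import DetectionParams, detect_spots
from .geometry import CellGeometry
from .kinetics import (
    KymographPath,
    SegmentationParams,
    fraction_minus,
    processive_runs,
    project_trajectory,
    segment_runs,
    velocity_stats,
)
from .link import LinkParams, link_spots
from .motility import MotilityParams, count_active
from .trajectory import trajectories_to_frame

log = logging.getLogger("cargokin")

__all__ = ["PipelineConfig", "run_pipeline", "runs_to_frame"]


@dataclass
class PipelineConfig:
    """Configuration for the full pipeline (units: µm, s)."""

    pixel_size: float = 0.1
    dt: float = 0.5
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    link: LinkParams = field(default_factory=LinkParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    kymo_width: float = 1.0
    output_dir: str = "cargokin_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("detection", DetectionParams),
            ("link", LinkParams),
            ("motility", MotilityParams),
            ("segmentation", SegmentationParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the canonicalized config (seed included;
        the output directory does not affect results and is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def seed_for(self, stage: str) -> int:
        """Stage seed derived from the top-level seed (documented derivation:
        SHA-256 of "<seed>:<stage>", reduced below 2³¹)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(h[:8], 16) % (2**31)


def runs_to_frame(segments_by_traj: dict[int, list]) -> pd.DataFrame:
    rows = []
    rid = 0
    for tid, segs in segments_by_traj.items():
        for sg in processive_runs(segs):
            rows.append(
                (rid, tid, sg.t_start, sg.t_end, sg.velocity, sg.length, sg.direction)
            )
            rid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "trajectory_id",
            "t_start",
            "t_end",
            "velocity_um_s",
            "length_um",
            "direction",
        ],
    )


def run_pipeline(
    config: PipelineConfig,
    stack_path,
    geometry_path=None,
    kymo_path: KymographPath | None = None,
) -> Path:
    """Run detect → track → motility → kinetics on a stack; return output dir.

    Motility metrics need a cell geometry JSON; kinetics needs a microtubule
    path. Stages with missing inputs are skipped with a log note. Every
    output file records the config hash.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log.info("pipeline start: config %s", chash)

    stack = ckio.read_stack(stack_path)
    log.info("read %s: %d frames of %dx%d", stack_path, *stack.shape)

    # --- detect ---------------------------------------------------------
    spots_by_frame = []
    for f in range(stack.shape[0]):
        spots_by_frame.append(
            detect_spots(stack[f], config.detection, config.pixel_size, frame_index=f)
        )
    spots_df = pd.DataFrame(
        [
            (s.frame, s.x, s.y, s.intensity, s.score)
            for frame in spots_by_frame
            for s in frame
        ],
        columns=["frame", "x_um", "y_um", "intensity", "score"],
    )
    ckio.write_table(spots_df, outdir / "spots.csv", "spots", chash)
    log.info("detect: %d spots", len(spots_df))

    # --- track ----------------------------------------------------------
    trajs = link_spots(spots_by_frame, config.link, dt=config.dt)
    tr_df = trajectories_to_frame(trajs)
    ckio.write_table(tr_df, outdir / "trajectories.csv", "trajectories", chash)
    log.info("track: %d trajectories", len(trajs))

    # --- motility -------------------------------------------------------
    if geometry_path is not None:
        geom = CellGeometry.from_json(geometry_path)
        t_total = stack.shape[0] * config.dt
        try:
            counts = count_active(trajs, geom, config.motility, t_total)
            ckio.write_table(counts, outdir / "active_counts.csv", "active_counts", chash)
            log.info("motility: %d windows", len(counts))
        except ValueError as exc:
            log.warning("motility stage skipped: %s", exc)
    else:
        log.info("motility stage skipped: no geometry provided")

    # --- kinetics -------------------------------------------------------
    if kymo_path is not None:
        segs_by_traj = {}
        for tr in trajs:
            if len(tr) < 3:
                continue
            try:
                s = project_trajectory(tr, kymo_path)
            except ValueError:
                continue
            segs_by_traj[tr.id] = segment_runs(s, config.segmentation, dt=config.dt)
        runs_df = runs_to_frame(segs_by_traj)
        ckio.write_table(runs_df, outdir / "runs.csv", "runs", chash)
        all_segs = [sg for segs in segs_by_traj.values() for sg in segs]
        summary = {"config_hash": chash, "n_trajectories": len(trajs)}
        if processive_runs(all_segs):
            f, ci = fraction_minus(all_segs)
            vs = velocity_stats(all_segs, L_min=config.segmentation.L_min)
            summary.update(
                f_minus=f,
                f_minus_ci=list(ci),
                v_plus_mean=vs["plus"]["mean"],
                v_minus_mean=vs["minus"]["mean"],
                n_runs=len(processive_runs(all_segs)),
            )
        ckio.write_json(summary, outdir / "kinetics_summary.json")
        log.info("kinetics: %d runs", len(runs_df))
    else:
        log.info("kinetics stage skipped: no microtubule path provided")

    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "config": config.to_dict(),
                "elapsed_s": round(time.time() - t_start, 3),
            },
            indent=1,
        )
    )
    log.info("pipeline done in %.2f s", time.time() - t_start)
    return outdir
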