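"""File formats: TIFF stacks, versioned CSV tables, summary JSON.

Units at rest are µm and s everywhere; pixel/frame conversion happens only
at image I/O. Every table carries a schema name + version in a leading
comment line, and a config hash when produced by the pipeline, so outputs
are traceable to the exact configuration that made them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "SchemaError",
    "SCHEMAS",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class SchemaError(ValueError):
    """Table does not match its registered schema."""


#: registry of CSV schemas (name -> (version, columns))
SCHEMAS: dict[str, tuple[int, list[str]]] = {
    "spots": (1, ["frame", "x_um", "y_um", "intensity", "score"]),
    "trajectories": (1, ["trajectory_id", "t_s", "x_um", "y_um", "intensity"]),
    "ground_truth": (1, ["trajectory_id", "frame", "t_s", "x_um", "y_um"]),
    "runs": (
        1,
        [
            "run_id",
            "trajectory_id",
            "t_start",
            "t_end",
            "velocity_um_s",
            "length_um",
            "direction",
        ],
    ),
    "active_counts": (1, ["window", "t_start", "t_end", "n_active", "normalized"]),
    "radial_profile": (1, ["bin_start_um", "bin_end_um", "summed_intensity"]),
    "orientation": (1, ["t_s", "theta_deg"]),
    "photoconv_pair": (1, ["t_s", "nucleus_front_um", "patch_um"]),
}


def read_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, H, W) array.

    RGB images, non-uniform page sizes, and unreadable files raise
    :class:`FormatError`.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if any(len(s) != 2 for s in shapes):
                raise FormatError(f"{path}: not single-channel grayscale pages")
            if len(shapes) != 1:
                raise FormatError(f"{path}: non-uniform page sizes {shapes}")
            arr = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # corrupt/unreadable file
        raise FormatError(f"{path}: cannot read TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="minisblack")


def write_table(
    df: pd.DataFrame, path, schema: str, config_hash: str | None = None
) -> None:
    """Write a CSV under a registered schema, with a provenance header."""
    version, cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema}.v{version}: missing columns {missing}")
    header = f"# cargokin schema={schema}.v{version}"
    if config_hash:
        header += f" config_hash={config_hash}"
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df[cols].to_csv(fh, index=False, float_format="%.6g")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schema'd CSV, validating name and version."""
    version, cols = SCHEMAS[schema]
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        if f"schema={schema}.v{version}" not in first:
            raise SchemaError(
                f"{path}: expected schema {schema}.v{version}, header was: "
                f"{first.strip()}"
            )
    df = pd.read_csv(path, comment="#")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
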