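"""File formats: current traces and layouts as CSV, image stacks as TIFF,
run configuration as YAML."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .nps import CurrentTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_stack",
    "write_stack",
    "read_layout",
    "write_layout",
    "load_config",
    "save_config",
    "config_hash",
]

TRACE_COLUMNS = ("time_s", "current_nA")


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a two-column time/current CSV (header ``time_s,current_nA``)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing column(s) {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError("trace needs at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValueError("trace time must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return CurrentTrace(time, df["current_nA"].to_numpy(dtype=float), rate)


def write_trace(trace: CurrentTrace, path: str | Path, float_format: str = "%.9g") -> None:
    pd.DataFrame({"time_s": trace.time_s, "current_nA": trace.current_na}).to_csv(
        path, index=False, float_format=float_format
    )


def write_stack(
    stack: np.ndarray, path: str | Path, voxel_size_um: tuple[float, float, float] | None = None
) -> None:
    """Write an 8/16-bit (or float) stack as multi-page TIFF.

    ``voxel_size_um`` is (z, y, x); carried as ImageJ-style metadata.
    """
    stack = np.asarray(stack)
    kwargs = {}
    if voxel_size_um is not None:
        z, y, x = voxel_size_um
        kwargs = {
            "resolution": (1.0 / x, 1.0 / y),
            "imagej": stack.dtype in (np.uint8, np.uint16),
            "metadata": {"spacing": z, "unit": "um"},
        }
    tifffile.imwrite(path, stack, **kwargs)


def read_stack(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read a TIFF stack; returns (array, voxel_size_um or None)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
            raise ValueError(f"unsupported bit depth {arr.dtype}")
        voxel = None
        meta = tf.imagej_metadata
        page = tf.pages[0]
        if meta and "spacing" in meta and "XResolution" in page.tags:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            voxel = (
                float(meta["spacing"]),
                yres[1] / yres[0],
                xres[1] / xres[0],
            )
    return arr, voxel


LAYOUT_REQUIRED = ("nucleus_id", "animal_id", "position")


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a gonad layout CSV (nucleus_id, animal_id, position, flags...)."""
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"layout file {path} missing column(s) {missing}")
    return df


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    layout.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for provenance records."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
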