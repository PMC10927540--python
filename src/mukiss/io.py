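"""File I/O: calibrated TIFF stacks with JSON sidecars, CSV tables.

An :class:`~mukiss.imaging.ImageSeries` round-trips as a multi-frame
TIFF plus a ``<name>.json`` sidecar carrying pixel size, frame interval
and channel; a missing sidecar is an explicit error, never a silent
default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flow import Envelope
from .imaging import ImageSeries


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def save_series(series: ImageSeries, path) -> None:
    tifffile.imwrite(path, series.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": series.pixel_size,
        "frame_interval_s": series.frame_interval,
        "channel": series.channel,
        "time_offset_s": series.time_offset,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_series(path) -> ImageSeries:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"calibration sidecar {sc} missing; refusing to guess pixel size"
        )
    meta = json.loads(sc.read_text())
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    return ImageSeries(
        frames=frames,
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        channel=meta.get("channel", ""),
        time_offset=meta.get("time_offset_s", 0.0),
    )


def save_envelope(envelope: Envelope, csv_path, tiff_path=None) -> None:
    """Boundary points as CSV (x, y, z in μm); occupancy grid as TIFF."""
    pd.DataFrame(envelope.boundary_points, columns=["x", "y", "z"]).to_csv(
        csv_path, index=False
    )
    if tiff_path is not None:
        tifffile.imwrite(tiff_path, envelope.occupancy_grid().astype(np.uint8))


def save_profile(positions, speeds, path) -> None:
    pd.DataFrame({"s_um": positions, "speed_um_s": speeds}).to_csv(path, index=False)
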