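"""File formats: multi-page TIFF stacks, detection tables, crop archives,
ground-truth tables.

Raw hologram stacks are written as 16-bit grayscale multi-page TIFF
with a fixed digital gain recorded in the image description, so
round-tripping recovers the simulated intensities (up to quantization).
Intermediate (cleaned/normalized) stacks are float32 TIFF.  Detections
travel as CSV, crops as HDF5 (n x 36 x 36).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .localize import CellDetection

__all__ = [
    "write_stack",
    "read_stack",
    "detections_to_frame",
    "write_detections",
    "read_detections",
    "write_crops",
    "read_crops",
]

DEFAULT_GAIN = 10_000.0  # camera counts per unit intensity


def write_stack(path, frames: np.ndarray, gain: float | None = DEFAULT_GAIN) -> None:
    """Write a (n, ny, nx) stack as multi-page TIFF.

    With a gain, frames are quantized to uint16 (clipped at full well);
    with ``gain=None`` they are stored as float32.
    """
    frames = np.asarray(frames)
    if gain is not None:
        data = np.clip(frames * gain, 0, 65535).astype(np.uint16)
        desc = json.dumps({"gain": gain})
    else:
        data = frames.astype(np.float32)
        desc = json.dumps({"gain": None})
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack back to float intensities."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    gain = None
    if desc:
        try:
            gain = json.loads(desc).get("gain")
        except (json.JSONDecodeError, AttributeError):
            gain = None
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[np.newaxis]
    return data / gain if gain else data


def detections_to_frame(detections: list[CellDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [d.frame_index for d in detections],
            "x_um": [d.x_um for d in detections],
            "y_um": [d.y_um for d in detections],
            "z_um": [d.z_um for d in detections],
            "focus_score": [d.focus_score for d in detections],
            "crop_id": np.arange(len(detections)),
        }
    )


def write_detections(path, detections: list[CellDetection]) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def read_detections(path, crops: np.ndarray | None = None) -> list[CellDetection]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        crop = crops[int(row.crop_id)] if crops is not None else np.zeros((36, 36), np.float32)
        out.append(
            CellDetection(
                frame_index=int(row.frame),
                x_um=float(row.x_um),
                y_um=float(row.y_um),
                z_um=float(row.z_um),
                focus_score=float(row.focus_score),
                pobf_crop=crop,
            )
        )
    return out


def write_crops(path, crops: np.ndarray, labels: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("crops", data=np.asarray(crops, dtype=np.float32))
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))


def read_crops(path):
    with h5py.File(path, "r") as fh:
        crops = fh["crops"][()]
        labels = fh["labels"][()] if "labels" in fh else None
    return crops, labels
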