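"""Background estimation and subtraction for raw hologram stacks.

Cells are sparse and move between frames, so the pixelwise mean over
the whole acquisition is an object-free estimate of the illumination
(vignette, fringes from fixed dust, sensor offsets).  Cleaning is the
signed difference ``frame - background``; reconstruction consumes the
flat-fielded contrast ``1 + cleaned / background``, which is ~1 away
from cells regardless of the illumination profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackgroundModel",
    "estimate_background",
    "subtract_background",
    "normalized_contrast",
]


@dataclass
class BackgroundModel:
    mean_frame: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.n_frames_used < 1:
            raise ValueError("background needs at least one frame")
        if not np.all(np.isfinite(self.mean_frame)):
            raise ValueError("background must be finite")


def estimate_background(stack) -> BackgroundModel:
    """Pixelwise arithmetic mean over all frames of the stack.

    Accepts a HologramStack or a bare (n, ny, nx) array.
    """
    frames = getattr(stack, "frames", stack)
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("need a non-empty (n_frames, ny, nx) stack")
    mean = frames.mean(axis=0, dtype=np.float64)
    return BackgroundModel(mean_frame=mean, n_frames_used=len(frames))


def subtract_background(frame: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Signed difference frame - background (same shape)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != bg.mean_frame.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.mean_frame.shape}"
        )
    return frame - bg.mean_frame


def normalized_contrast(
    frame: np.ndarray, bg: BackgroundModel, guard_frac: float = 0.01
) -> np.ndarray:
    """Flat-fielded contrast ``1 + (frame - background)/background``.

    Pixels where the background falls below ``guard_frac`` of its
    median are clamped to that floor before division, so dead sensor
    regions cannot blow up the contrast.
    """
    cleaned = subtract_background(frame, bg)
    floor = guard_frac * float(np.median(bg.mean_frame))
    denom = np.maximum(bg.mean_frame, floor if floor > 0 else np.finfo(float).tiny)
    return 1.0 + cleaned / denom
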