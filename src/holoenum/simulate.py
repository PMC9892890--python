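"""Synthetic in-line hologram stacks with ground-truth cell tracks.

The simulator emulates cells advected through a sheathed microchannel
past a fixed field of view.  Each cell is a weak amplitude (optionally
phase) disk; its object-plane perturbation is propagated to the
hologram plane with the same angular-spectrum operator used for
reconstruction, perturbations from all cells in a frame are superposed
on a unit reference wave, and the recorded frame is
``illumination * |1 + sum_i P_{d_i}(t_i - 1)|^2 + noise``.

Coordinates: x = streamwise (image columns), y = cross-stream (image
rows), z = height above the channel floor; lengths in um.  A cell at
height z propagates ``recording_distance + z`` to reach the hologram
plane.  Arrivals are a Poisson process with rate concentration x
sample flow rate; each cell enters the field of view at x = 0 and is
advected by the local laminar flow speed, so fast (centerline) cells
appear in a single frame while slow cells near the sample-sheath
interface persist for 2-3 consecutive frames.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as fft

from .config import FlowConfig, OpticalConfig, SimParams
from .reconstruct import angular_spectrum_transfer

__all__ = [
    "TUMOR",
    "WBC",
    "SimCell",
    "HologramStack",
    "poiseuille_velocity",
    "project_hologram",
    "simulate_stack",
    "simulate_tracks",
    "make_training_crops",
]

TUMOR = "TUMOR"
WBC = "WBC"


@dataclass
class SimCell:
    """A simulated scatterer with its trajectory parameters."""

    cell_id: int
    class_label: str  # TUMOR or WBC
    diameter_um: float
    amplitude_contrast: float  # in [0, 1]
    phase_contrast_rad: float
    y_um: float  # cross-stream position (image rows)
    z_um: float  # height above channel floor
    entry_time_s: float  # time at which the cell crosses x = 0
    texture_seed: int | None = None  # per-cell internal granularity pattern
    speed_um_s: float = 0.0
    x_um: float = 0.0  # streamwise position at a given frame (snapshot)
    entry_frame: int = 0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1]")


@dataclass
class HologramStack:
    """An ordered stack of intensity frames plus simulation ground truth.

    ``ground_truth`` has one row per (frame, cell) appearance: a cell
    visible in k consecutive frames is logged k times, which is exactly
    what multiple-count removal must undo.  ``illumination`` is the
    true cell-free background (for validating background estimation).
    """

    frames: np.ndarray  # (n_frames, ny, nx), float32, >= 0
    frame_rate_fps: float
    ground_truth: "object | None" = None  # pandas.DataFrame
    illumination: np.ndarray | None = None
    cells: list[SimCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def poiseuille_velocity(
    y_um: float, z_um: float, flow: FlowConfig, optics: OpticalConfig
) -> float:
    """Streamwise speed (um/s) at cross-section position (y, z).

    Uses a separable product-of-parabolas profile
    ``u(y, z) = u_max (1 - (2y/W - 1)^2)(1 - (2z/H - 1)^2)`` scaled so
    that its integral over the cross-section equals the total
    volumetric flow rate; hence ``u_max = (9/4) Q / (W H)``.
    """
    W = optics.channel_width_um
    H = optics.channel_height_um
    y = np.asarray(y_um, dtype=float)
    z = np.asarray(z_um, dtype=float)
    if np.any((y < 0) | (y > W) | (z < 0) | (z > H)):
        raise ValueError("position outside the channel cross-section")
    u_max = 2.25 * flow.total_flow_rate_um3_s / (W * H)
    u = u_max * (1.0 - (2.0 * y / W - 1.0) ** 2) * (1.0 - (2.0 * z / H - 1.0) ** 2)
    return float(u) if np.isscalar(y_um) and np.isscalar(z_um) else u


def _disk_transmission_perturbation(
    shape: tuple[int, int],
    x_um: float,
    y_um: float,
    diameter_um: float,
    amplitude_contrast: float,
    phase_rad: float,
    pixel_pitch_um: float,
    texture_seed: int | None = None,
    texture_strength: float = 0.6,
    texture_scale_px: float = 0.8,
) -> np.ndarray:
    """Object-plane perturbation t - 1 for an antialiased textured disk.

    The transmission is ``t = 1 - a*m*tex`` (plus an optional phase
    term), where m is the disk membership map with a half-pixel
    antialiased edge and ``tex`` a per-cell granular modulation
    emulating organelle-scale structure.  The granularity matters
    beyond realism: a featureless disk scatters only at low angles and
    carries almost no axial information, so cells without internal
    texture cannot be brought to a well-defined focus.
    """
    ny, nx = shape
    radius_px = 0.5 * diameter_um / pixel_pitch_um
    if 2 * radius_px > min(ny, nx):
        raise ValueError("cell larger than the field of view")
    yy = np.arange(ny) - y_um / pixel_pitch_um
    xx = np.arange(nx) - x_um / pixel_pitch_um
    r = np.hypot(yy[:, np.newaxis], xx[np.newaxis, :])
    m = np.clip(radius_px + 0.5 - r, 0.0, 1.0)  # antialiased edge
    if texture_seed is not None and texture_strength > 0:
        from scipy import ndimage

        # texture only needs to exist under the disk; keep it local
        pad = int(np.ceil(radius_px)) + 4
        r0 = max(int(round(y_um / pixel_pitch_um)) - pad, 0)
        r1 = min(int(round(y_um / pixel_pitch_um)) + pad, ny)
        c0 = max(int(round(x_um / pixel_pitch_um)) - pad, 0)
        c1 = min(int(round(x_um / pixel_pitch_um)) + pad, nx)
        if r1 > r0 and c1 > c0:
            trng = np.random.default_rng(texture_seed)
            tex = ndimage.gaussian_filter(
                trng.normal(size=(r1 - r0, c1 - c0)), texture_scale_px
            )
            sd = tex.std()
            if sd > 0:
                tex = np.clip(1.0 + texture_strength * tex / sd, 0.0, 2.0)
                m[r0:r1, c0:c1] *= tex
    t = (1.0 - amplitude_contrast * m).astype(np.complex128)
    if phase_rad:
        t *= np.exp(1j * phase_rad * m)
    return t - 1.0


def project_hologram(
    cells: Sequence[SimCell],
    optics: OpticalConfig,
    texture_strength: float = 0.6,
    texture_scale_px: float = 0.8,
) -> np.ndarray:
    """Forward-model the in-line hologram intensity of a set of cells.

    Each cell's object-plane perturbation is propagated by
    ``recording_distance + z`` (single scattering; perturbations
    superpose in the field before squaring).  With no cells the frame
    is the unit reference intensity.
    """
    shape = optics.fov_px
    if min(shape) < 1:
        raise ValueError("empty field of view")
    field_sum = None
    for cell in cells:
        pert = _disk_transmission_perturbation(
            shape,
            cell.x_um,
            cell.y_um,
            cell.diameter_um,
            cell.amplitude_contrast,
            cell.phase_contrast_rad,
            optics.pixel_pitch_um,
            texture_seed=cell.texture_seed,
            texture_strength=texture_strength,
            texture_scale_px=texture_scale_px,
        )
        d = optics.recording_distance_um + cell.z_um
        if d < optics.recording_distance_um:
            raise ValueError("cell below the channel floor")
        P = fft.fft2(pert)
        P *= angular_spectrum_transfer(shape, d, optics)
        field_sum = P if field_sum is None else field_sum + P
    if field_sum is None:
        return np.ones(shape, dtype=np.float64)
    field = 1.0 + fft.ifft2(field_sum)
    return field.real**2 + field.imag**2


def _illumination(optics: OpticalConfig, sim: SimParams) -> np.ndarray:
    """Smooth Gaussian vignette x constant level."""
    ny, nx = optics.fov_px
    y = (np.arange(ny) - (ny - 1) / 2.0) / max(ny, 1)
    x = (np.arange(nx) - (nx - 1) / 2.0) / max(nx, 1)
    r2 = y[:, np.newaxis] ** 2 + x[np.newaxis, :] ** 2
    vign = 1.0 - sim.vignette_strength * (1.0 - np.exp(-2.0 * r2))
    return sim.illumination_level * vign


def _draw_cells(
    optics: OpticalConfig,
    flow: FlowConfig,
    sim: SimParams,
    class_mix: dict[str, float],
    duration_s: float,
    rng: np.random.Generator,
) -> list[SimCell]:
    """Poisson arrivals for each class over the acquisition window."""
    W = optics.channel_width_um
    core = optics.sample_core_width_um
    y_lo, y_hi = (W - core) / 2.0, (W + core) / 2.0
    z_lo = sim.z_margin_um
    z_hi = optics.channel_height_um - sim.z_margin_um
    q_ml_s = flow.sample_flow_rate_ml_min / 60.0
    cells: list[SimCell] = []
    cid = 0
    for label in sorted(class_mix):
        conc = class_mix[label]
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        n = rng.poisson(conc * q_ml_s * duration_s)
        if label == TUMOR:
            d_mu, d_sd, contrast = (
                sim.tumor_diameter_um,
                sim.tumor_diameter_sd_um,
                sim.tumor_amplitude_contrast,
            )
        elif label == WBC:
            d_mu, d_sd, contrast = (
                sim.wbc_diameter_um,
                sim.wbc_diameter_sd_um,
                sim.wbc_amplitude_contrast,
            )
        else:
            raise ValueError(f"unknown class label {label!r}")
        for _ in range(int(n)):
            diam = _truncated_normal(rng, d_mu, d_sd, lo=0.25 * d_mu)
            y = rng.uniform(y_lo, y_hi)
            z = rng.uniform(z_lo, z_hi)
            cells.append(
                SimCell(
                    cell_id=cid,
                    class_label=label,
                    diameter_um=diam,
                    amplitude_contrast=contrast,
                    phase_contrast_rad=sim.phase_contrast_rad,
                    y_um=y,
                    z_um=z,
                    entry_time_s=rng.uniform(0.0, duration_s),
                    texture_seed=int(rng.integers(0, 2**31)),
                    speed_um_s=poiseuille_velocity(y, z, flow, optics),
                )
            )
            cid += 1
    return cells


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, lo: float
) -> float:
    for _ in range(100):
        v = rng.normal(mu, sd)
        if v > lo:
            return v
    return mu


def simulate_tracks(
    optics: OpticalConfig,
    flow: FlowConfig,
    class_mix: dict[str, float],
    seed: int,
    sim: SimParams | None = None,
    n_frames: int | None = None,
):
    """Ground-truth trajectories only (no image rendering).

    Returns (cells, ground_truth DataFrame) where the table has one row
    per frame in which each cell is inside the field of view.
    """
    import pandas as pd

    sim = sim or SimParams()
    n_frames = flow.n_frames if n_frames is None else n_frames
    duration = n_frames / flow.frame_rate_fps
    rng = np.random.default_rng(seed)
    cells = _draw_cells(optics, flow, sim, class_mix, duration, rng)
    fov_x_um = optics.fov_px[1] * optics.pixel_pitch_um
    rows = []
    for c in cells:
        first = True
        # frames while 0 <= x < fov_x
        k0 = int(np.ceil(c.entry_time_s * flow.frame_rate_fps))
        for k in range(k0, n_frames):
            x = (k / flow.frame_rate_fps - c.entry_time_s) * c.speed_um_s
            if x >= fov_x_um:
                break
            if first:
                c.entry_frame = k
                first = False
            rows.append(
                (k, c.cell_id, c.class_label, x, c.y_um, c.z_um, c.diameter_um)
            )
    gt = pd.DataFrame(
        rows,
        columns=["frame", "cell_id", "class", "x_um", "y_um", "z_um", "diameter_um"],
    )
    return cells, gt


def simulate_stack(
    optics: OpticalConfig,
    flow: FlowConfig,
    class_mix: dict[str, float],
    seed: int,
    sim: SimParams | None = None,
    n_frames: int | None = None,
) -> HologramStack:
    """Render a full hologram stack with ground truth.

    Frames with no cell in view are illumination + sensor noise only.
    Identical seeds give bit-identical stacks.
    """
    sim = sim or SimParams()
    n_frames = flow.n_frames if n_frames is None else n_frames
    cells, gt = simulate_tracks(optics, flow, class_mix, seed, sim, n_frames)
    illum = _illumination(optics, sim)
    noise_sd = sim.noise_sigma_frac * float(illum.mean())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1A5]))
    by_frame: dict[int, list[SimCell]] = {}
    if len(gt):
        by_id = {c.cell_id: c for c in cells}
        for k, cid, x in zip(gt["frame"], gt["cell_id"], gt["x_um"]):
            snap = dataclasses.replace(by_id[int(cid)], x_um=float(x))
            by_frame.setdefault(int(k), []).append(snap)
    frames = np.empty((n_frames, *optics.fov_px), dtype=np.float32)
    for k in range(n_frames):
        snaps = by_frame.get(k, [])
        pattern = (
            project_hologram(
                snaps,
                optics,
                texture_strength=sim.texture_strength,
                texture_scale_px=sim.texture_scale_px,
            )
            if snaps
            else 1.0
        )
        frame = illum * pattern
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=optics.fov_px)
        frames[k] = np.maximum(frame, 0.0).astype(np.float32)
    return HologramStack(
        frames=frames,
        frame_rate_fps=flow.frame_rate_fps,
        ground_truth=gt,
        illumination=illum,
        cells=cells,
    )


def make_training_crops(
    n_per_class: int,
    optics: OpticalConfig,
    sim: SimParams | None = None,
    seed: int = 0,
    crop_px: int = 36,
    field_px: int = 64,
    z_defocus_jitter_um: float = 2.5,
):
    """Synthesize labeled plane-of-best-focus crops for classifier training.

    Renders each cell alone on a small grid, forms its hologram at its
    true depth, adds sensor noise, and back-propagates to a plane
    offset by up to half the plane spacing (emulating the quantized
    focus search of the full pipeline).  Crops are min-max normalized
    to [0, 1].  Returns (crops (n, 36, 36) float32, labels (n,) int
    with 1 = tumor).
    """
    sim = sim or SimParams()
    rng = np.random.default_rng(seed)
    small = OpticalConfig(
        wavelength_um=optics.wavelength_um,
        pixel_pitch_um=optics.pixel_pitch_um,
        fov_px=(field_px, field_px),
        recording_distance_um=optics.recording_distance_um,
        plane_spacing_um=optics.plane_spacing_um,
        channel_width_um=optics.channel_width_um,
        channel_height_um=optics.channel_height_um,
        sample_core_width_um=optics.sample_core_width_um,
        medium_refractive_index=optics.medium_refractive_index,
    )
    z_lo = sim.z_margin_um
    z_hi = optics.channel_height_um - sim.z_margin_um
    n = 2 * n_per_class
    crops = np.empty((n, crop_px, crop_px), dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    noise_sd = sim.noise_sigma_frac
    half = field_px / 2.0
    lo = field_px // 2 - crop_px // 2
    for i in range(n):
        label = i % 2  # 1 = tumor
        if label:
            diam = _truncated_normal(
                rng, sim.tumor_diameter_um, sim.tumor_diameter_sd_um, 0.25 * sim.tumor_diameter_um
            )
            contrast = sim.tumor_amplitude_contrast
        else:
            diam = _truncated_normal(
                rng, sim.wbc_diameter_um, sim.wbc_diameter_sd_um, 0.25 * sim.wbc_diameter_um
            )
            contrast = sim.wbc_amplitude_contrast
        z = rng.uniform(z_lo, z_hi)
        dx, dy = rng.uniform(-0.5, 0.5, size=2)
        cell = SimCell(
            cell_id=i,
            class_label=TUMOR if label else WBC,
            diameter_um=diam,
            amplitude_contrast=contrast,
            phase_contrast_rad=sim.phase_contrast_rad,
            y_um=half + dy,
            z_um=z,
            entry_time_s=0.0,
            texture_seed=int(rng.integers(0, 2**31)),
            x_um=half + dx,
        )
        holo = project_hologram(
            [cell],
            small,
            texture_strength=sim.texture_strength,
            texture_scale_px=sim.texture_scale_px,
        )
        if noise_sd > 0:
            holo = holo + rng.normal(0.0, noise_sd, size=holo.shape)
        d = optics.recording_distance_um + z + rng.uniform(
            -z_defocus_jitter_um, z_defocus_jitter_um
        )
        # mirror the pipeline: back-propagate the zero-mean contrast and
        # form the image intensity |1 + g|^2 around the cell
        F = fft.fft2((holo - 1.0).astype(np.complex128))
        F *= angular_spectrum_transfer(holo.shape, -d, small)
        g = fft.ifft2(F)
        re1 = 1.0 + g.real
        intensity = re1 * re1 + g.imag**2
        window = intensity[lo : lo + crop_px, lo : lo + crop_px]
        span = window.max() - window.min()
        crops[i] = ((window - window.min()) / span if span > 0 else window).astype(
            np.float32
        )
        labels[i] = label
    return crops, labels
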