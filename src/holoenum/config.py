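"""Acquisition geometry and flow configuration.

All lengths are in micrometres (um), times in seconds, volumetric flow
rates in mL/min (the unit used on syringe pumps), and frame rates in
frames per second.  These defaults describe a sheathed microchannel
(800 um wide x 330 um deep) imaged in-line at 1 um/px with a 635 nm
diode laser, the hologram plane sitting 200 um below the channel floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "OpticalConfig",
    "FlowConfig",
    "DedupConfig",
    "SimParams",
    "TrainConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical recording and reconstruction geometry.

    Attributes
    ----------
    wavelength_um : float
        Vacuum wavelength of the coherent source.
    pixel_pitch_um : float
        Object-plane sampling after magnification (1 um/px at 20x).
    fov_px : tuple of int
        Field of view in pixels, (rows, cols) = (y, x).
    recording_distance_um : float
        Distance from the channel floor to the hologram plane.
    plane_spacing_um : float
        Axial spacing between reconstruction planes.
    channel_width_um, channel_height_um : float
        Cross-section of the flow channel (width = cross-stream y,
        height = axial z).
    sample_core_width_um : float
        Width of the sheath-confined sample core; cells only occupy
        this central band of the channel.
    medium_refractive_index : float
        Refractive index of the suspension medium; propagation uses the
        effective wavelength ``wavelength_um / n``.
    """

    wavelength_um: float = 0.635
    pixel_pitch_um: float = 1.0
    fov_px: tuple[int, int] = (800, 800)
    recording_distance_um: float = 200.0
    plane_spacing_um: float = 5.0
    channel_width_um: float = 800.0
    channel_height_um: float = 330.0
    sample_core_width_um: float = 500.0
    medium_refractive_index: float = 1.33

    def __post_init__(self) -> None:
        for name in (
            "wavelength_um",
            "pixel_pitch_um",
            "recording_distance_um",
            "plane_spacing_um",
            "channel_width_um",
            "channel_height_um",
            "sample_core_width_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.fov_px) < 1:
            raise ValueError("fov_px must be positive")
        if self.sample_core_width_um > self.channel_width_um:
            raise ValueError("sample core cannot be wider than the channel")
        if self.medium_refractive_index < 1:
            raise ValueError("medium_refractive_index must be >= 1")

    @property
    def max_reconstruction_distance_um(self) -> float:
        """Farthest propagation distance: channel ceiling to hologram plane."""
        return self.recording_distance_um + self.channel_height_um

    @property
    def reconstruction_distances_um(self):
        """Plane distances spanning the channel depth, both endpoints included."""
        import numpy as np

        n = int(self.channel_height_um / self.plane_spacing_um) + 1
        return self.recording_distance_um + self.plane_spacing_um * np.arange(n)

    @property
    def effective_wavelength_um(self) -> float:
        return self.wavelength_um / self.medium_refractive_index


@dataclass(frozen=True)
class FlowConfig:
    """Volumetric flow and acquisition timing.

    The sample stream is flanked by ``n_sheath_streams`` sheath streams;
    only the sample stream carries cells.  10 100 frames at 420 fps with
    a 2.5 mL/min sample flow image ~1 mL of sample.
    """

    sample_flow_rate_ml_min: float = 2.5
    sheath_flow_rate_ml_min: float = 0.5
    n_sheath_streams: int = 2
    frame_rate_fps: float = 420.0
    n_frames: int = 10_100

    def __post_init__(self) -> None:
        if self.sample_flow_rate_ml_min < 0 or self.sheath_flow_rate_ml_min < 0:
            raise ValueError("flow rates must be >= 0")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be > 0")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")

    @property
    def total_flow_rate_ml_min(self) -> float:
        return (
            self.sample_flow_rate_ml_min
            + self.n_sheath_streams * self.sheath_flow_rate_ml_min
        )

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_fps

    @property
    def sample_flow_rate_um3_s(self) -> float:
        return self.sample_flow_rate_ml_min * 1e12 / 60.0

    @property
    def total_flow_rate_um3_s(self) -> float:
        return self.total_flow_rate_ml_min * 1e12 / 60.0


@dataclass(frozen=True)
class DedupConfig:
    """Proximity criteria for multiple-count removal between frames.

    A detection in frame i+1 is a repeat of one in frame i when its
    cross-stream and axial positions are within ``dy_max_um`` and
    ``dz_max_um``; the lenient z bound reflects the poorer axial
    localization of in-line holography.
    """

    dy_max_um: float = 3.0
    dz_max_um: float = 50.0
    max_frame_gap: int = 1

    def __post_init__(self) -> None:
        if self.dy_max_um <= 0 or self.dz_max_um <= 0:
            raise ValueError("dedup thresholds must be > 0")
        if self.max_frame_gap < 1:
            raise ValueError("max_frame_gap must be >= 1")


@dataclass(frozen=True)
class SimParams:
    """Scatterer and sensor parameters for the hologram simulator.

    Tumor cells are modelled as larger, higher-contrast disks than
    WBCs; diameters are drawn from truncated normals.  ``z_margin_um``
    keeps cells away from the floor/ceiling where lift forces deplete
    them in practice (and where the no-slip profile would make them
    linger for many frames).
    """

    tumor_diameter_um: float = 18.0
    tumor_diameter_sd_um: float = 2.0
    tumor_amplitude_contrast: float = 0.4
    wbc_diameter_um: float = 10.0
    wbc_diameter_sd_um: float = 1.5
    wbc_amplitude_contrast: float = 0.25
    phase_contrast_rad: float = 0.0
    texture_strength: float = 0.6
    texture_scale_px: float = 0.8
    z_margin_um: float = 50.0
    illumination_level: float = 1.0
    vignette_strength: float = 0.1
    noise_sigma_frac: float = 0.01
    motion_blur: bool = False

    def __post_init__(self) -> None:
        for name in ("tumor_amplitude_contrast", "wbc_amplitude_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise_sigma_frac must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Classifier training recipe: Adam(1e-3), minibatch 32, 20 epochs,
    70/30 stratified random split."""

    minibatch: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.minibatch < 1 or self.epochs < 1:
            raise ValueError("minibatch and epochs must be >= 1")


_SECTION_TYPES: dict[str, type] = {
    "optics": OpticalConfig,
    "flow": FlowConfig,
    "dedup": DedupConfig,
    "sim": SimParams,
    "train": TrainConfig,
}


def _build(cls: type, data: Mapping[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    if cls is OpticalConfig and "fov_px" in data:
        data = {**data, "fov_px": tuple(data["fov_px"])}
    return cls(**data)


def load_config(path) -> dict[str, Any]:
    """Read a YAML/JSON config file with optics/flow/... sections.

    Known sections are materialized into their dataclasses; unknown
    sections are passed through as plain dictionaries.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    for key, val in raw.items():
        if key in _SECTION_TYPES and isinstance(val, Mapping):
            out[key] = _build(_SECTION_TYPES[key], val)
        else:
            out[key] = val
    return out


def save_config(cfg: Mapping[str, Any], path) -> None:
    """Write a config dictionary (dataclasses allowed as values) to YAML."""
    raw = {}
    for key, val in cfg.items():
        if dataclasses.is_dataclass(val) and not isinstance(val, type):
            d = dataclasses.asdict(val)
            if "fov_px" in d:
                d["fov_px"] = list(d["fov_px"])
            raw[key] = d
        else:
            raw[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
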