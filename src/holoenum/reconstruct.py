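"""Angular-spectrum propagation and full-volume reconstruction.

In-line holograms are back-propagated to a stack of planes spanning the
channel depth (recording distance .. recording distance + channel
height, every ``plane_spacing_um``).  The angular-spectrum transfer
function is exact for scalar diffraction and exactly invertible on
propagating modes, so forward/backward round trips are available as a
self-check.  Reconstruction is amplitude-only: the zero-mean part of
the normalized hologram contrast is treated as the real-valued
scattered amplitude at the hologram plane, the unit reference stays as
an unpropagated DC term, and the twin image is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as fft

from .config import OpticalConfig

__all__ = [
    "ReconStack",
    "angular_spectrum_transfer",
    "angular_spectrum_propagate",
    "reconstruct_volume",
]

_MAX_DISTANCE_UM = 1e6  # 1 m; beyond this the paraxial sampling is meaningless


@dataclass
class ReconStack:
    """Reconstructed volume.

    ``field[k]`` is the back-propagated scattered field g at
    propagation distance ``distances_um[k]`` from the hologram plane.
    Derived views: ``scattered`` = |g|^2 (cells bright and compact at
    focus; used for detection and autofocus) and ``planes`` =
    |1 + g|^2, the image intensity in which cells appear dark at focus
    (used for classifier crops).
    """

    field: np.ndarray  # (n_planes, ny, nx) complex
    distances_um: np.ndarray  # strictly increasing
    _scattered: np.ndarray | None = field(default=None, repr=False)
    _planes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.field.ndim != 3 or len(self.field) != len(self.distances_um):
            raise ValueError("field and distances_um are inconsistent")
        if np.any(np.diff(self.distances_um) <= 0):
            raise ValueError("distances_um must be strictly increasing")

    @property
    def n_planes(self) -> int:
        return len(self.distances_um)

    @property
    def scattered(self) -> np.ndarray:
        if self._scattered is None:
            g = self.field
            self._scattered = (g.real**2 + g.imag**2).astype(np.float32)
        return self._scattered

    @property
    def planes(self) -> np.ndarray:
        if self._planes is None:
            g = self.field
            re1 = 1.0 + g.real
            self._planes = (re1 * re1 + g.imag**2).astype(np.float32)
        return self._planes


def angular_spectrum_transfer(
    shape: tuple[int, int], distance_um: float, optics: OpticalConfig
) -> np.ndarray:
    """Frequency-domain transfer function H(fx, fy; d).

    H = exp(i * 2*pi*n/lambda * d * sqrt(1 - (lambda*fx/n)^2 - (lambda*fy/n)^2)),
    with evanescent components (negative radicand) zeroed.  ``distance_um``
    may be negative (back-propagation).
    """
    ny, nx = shape
    lam = optics.effective_wavelength_um
    fy = fft.fftfreq(ny, d=optics.pixel_pitch_um)
    fx = fft.fftfreq(nx, d=optics.pixel_pitch_um)
    fx2 = (lam * fx[np.newaxis, :]) ** 2
    fy2 = (lam * fy[:, np.newaxis]) ** 2
    radicand = 1.0 - fx2 - fy2
    propagating = radicand > 0.0
    kz = np.zeros(shape, dtype=np.float64)
    np.sqrt(radicand, out=kz, where=propagating)
    H = np.exp((2j * np.pi / lam * distance_um) * kz)
    H[~propagating] = 0.0
    return H


def angular_spectrum_propagate(
    field: np.ndarray, distance_um: float, optics: OpticalConfig
) -> np.ndarray:
    """Propagate a complex field by a signed distance (um).

    Positive distances move away from the object (toward the sensor);
    negative distances back-propagate.  Evanescent content is discarded,
    so power is conserved only on the propagating part of the spectrum.
    """
    field = np.asarray(field)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if abs(distance_um) > _MAX_DISTANCE_UM:
        raise ValueError("|distance| exceeds 1 m")
    F = fft.fft2(field.astype(np.complex128, copy=False))
    F *= angular_spectrum_transfer(field.shape, distance_um, optics)
    return fft.ifft2(F)


def reconstruct_volume(cleaned_frame: np.ndarray, optics: OpticalConfig) -> ReconStack:
    """Back-propagate a normalized hologram to every plane in the channel.

    ``cleaned_frame`` is the background-normalized contrast image
    (~1 away from cells); its zero-mean part c = frame - 1 is
    back-propagated to every plane in
    ``optics.reconstruction_distances_um``.
    """
    cleaned_frame = np.asarray(cleaned_frame, dtype=np.float64)
    if cleaned_frame.ndim != 2:
        raise ValueError("cleaned_frame must be a 2D image")
    distances = np.asarray(optics.reconstruction_distances_um, dtype=np.float64)
    contrast = cleaned_frame - 1.0
    F = fft.fft2(contrast.astype(np.complex128))
    out = np.empty((len(distances), *cleaned_frame.shape), dtype=np.complex64)
    for k, d in enumerate(distances):
        H = angular_spectrum_transfer(cleaned_frame.shape, -d, optics)
        out[k] = fft.ifft2(F * H).astype(np.complex64)
    return ReconStack(field=out, distances_um=distances)
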