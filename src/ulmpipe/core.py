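"""Shared data containers and stack I/O.

Conventions used throughout the package:

* image axes are ``(z, x)`` -- axial depth increases along rows, lateral
  position along columns;
* positions are micrometres relative to the centre of the top-left pixel
  (0-based, pixel-centre convention);
* velocities are mm/s; frame rates are Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import tifffile

DEFAULT_MAP_SPACING_UM = 4.928
"""Isotropic pixel spacing (um) of the super-resolved output grid."""


@dataclass
class IQStack:
    """A stack of beamformed complex IQ frames.

    Parameters
    ----------
    frames
        Complex array of shape ``(n_frames, nz, nx)``.
    pixel_spacing
        ``(dz, dx)`` pixel pitch in micrometres.
    frame_rate
        Frame rate in Hz.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n_frames, nz, nx), got {self.frames.shape}")
        dz, dx = self.pixel_spacing
        if dz <= 0 or dx <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def nz(self) -> int:
        return self.frames.shape[1]

    @property
    def nx(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def casorati(self) -> np.ndarray:
        """Space x time (Casorati) matrix view of the stack."""
        return self.frames.reshape(self.n_frames, -1).T

    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames)

    def energy(self) -> float:
        return float(np.sum(np.abs(self.frames) ** 2))

    def with_frames(self, frames: np.ndarray) -> "IQStack":
        return IQStack(frames, self.pixel_spacing, self.frame_rate)


def save_stack(path: str, stack: IQStack) -> None:
    """Write a stack to HDF5 (separate real/imag datasets plus grid attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=stack.frames.real, compression="gzip", compression_opts=1)
        f.create_dataset("imag", data=stack.frames.imag, compression="gzip", compression_opts=1)
        f.attrs["pixel_spacing_um"] = list(stack.pixel_spacing)
        f.attrs["frame_rate_hz"] = stack.frame_rate


def load_stack(path: str) -> IQStack:
    with h5py.File(path, "r") as f:
        frames = f["real"][...] + 1j * f["imag"][...]
        spacing = tuple(float(v) for v in f.attrs["pixel_spacing_um"])
        rate = float(f.attrs["frame_rate_hz"])
    return IQStack(frames, spacing, rate)


def save_magnitude_tiff(path: str, stack: IQStack) -> None:
    """Magnitude-only multi-page 32-bit TIFF for visual inspection."""
    tifffile.imwrite(path, np.abs(stack.frames).astype(np.float32))


@dataclass
class Grid:
    """A raster grid: shape plus isotropic-or-not pixel spacing in um."""

    nz: int
    nx: int
    spacing_um: tuple[float, float] = (DEFAULT_MAP_SPACING_UM, DEFAULT_MAP_SPACING_UM)

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.nz * self.spacing_um[0], self.nx * self.spacing_um[1])
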