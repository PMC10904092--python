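"""Clutter/noise separation on the Casorati matrix, plus power Doppler and
heart-rate estimation from power-Doppler pulsatility.

The stack is reshaped to a space x time (Casorati) matrix and decomposed by
SVD; slowly varying tissue lives in the low-order singular components and is
removed by subtracting the rank-``cutoff`` reconstruction.  The cutoff can be
fixed or chosen adaptively as the knee of the log singular-value spectrum
(maximum perpendicular distance to the chord joining the spectrum endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.signal
from scipy.ndimage import median_filter

from ulmpipe.core import IQStack


class DegenerateSpectrumError(ValueError):
    """The singular spectrum has no knee (e.g. all values equal)."""


class NoPeakError(ValueError):
    """No periodogram peak rises above the noise floor in the search band."""


@dataclass
class NoiseProfile:
    """Per-depth multiplicative noise gain (unitless, strictly positive)."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("noise profile must be strictly positive")
        ratio = self.gain[1:] / self.gain[:-1]
        if np.any(ratio > 1.5) or np.any(ratio < 1 / 1.5):
            raise ValueError("noise profile is not smooth (sample-to-sample jump > 50%)")


@dataclass
class SVDDecomposition:
    """Summary of the Casorati SVD used for filtering."""

    singular_values: np.ndarray          # descending
    temporal_vectors: np.ndarray         # (rank, n_frames) rows of Vh
    spatial_vectors: np.ndarray          # (n_keep, nz, nx) leading spatial modes
    cutoff: int
    noise_profile: NoiseProfile | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 1e-9 * max(s[0], 1.0)):
            raise ValueError("singular values must be non-negative and non-increasing")
        if not (0 <= self.cutoff <= self.temporal_vectors.shape[1]):
            raise ValueError("cutoff out of range")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(len(self.singular_values)),
            "singular_value": self.singular_values,
            "removed": np.arange(len(self.singular_values)) < self.cutoff,
        })


def adaptive_rank_select(singular_values: np.ndarray) -> int:
    """Knee of the log10 singular-value curve.

    Returns the 0-based index of the point with maximum perpendicular distance
    to the chord joining the first and last points of the log spectrum; this
    index equals the number of leading (tissue) components to remove.
    """
    s = np.asarray(singular_values, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 singular values")
    if np.any(s <= 0):
        s = np.clip(s, np.finfo(float).tiny, None)
    y = np.log10(s)
    n = len(y)
    x = np.arange(n, dtype=float)
    # perpendicular distance to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    span = max(y.max() - y.min(), 1.0)
    if dist.max() < 1e-6 * span:
        raise DegenerateSpectrumError("log spectrum coincides with its chord (no knee)")
    cutoff = int(np.argmax(dist))
    return int(np.clip(cutoff, 1, n - 1))


def svd_filter(stack: IQStack, rank_mode: str = "adaptive", rank: int | None = None,
               n_spatial_keep: int = 8) -> tuple[IQStack, SVDDecomposition]:
    """Remove low-order (tissue) singular components from the stack.

    Returns the filtered stack plus the decomposition summary.  The filtered
    stack is exactly the reconstruction from components with index >= cutoff.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if rank_mode not in ("fixed", "adaptive"):
        raise ValueError("rank_mode must be 'fixed' or 'adaptive'")
    if rank_mode == "fixed":
        if rank is None:
            raise ValueError("fixed rank_mode requires rank")
        if rank >= stack.n_frames:
            raise ValueError("rank must be smaller than the number of frames")
        if rank < 0:
            raise ValueError("rank must be >= 0")

    C = stack.casorati()
    U, s, Vh = scipy.linalg.svd(C, full_matrices=False)
    cutoff = rank if rank_mode == "fixed" else adaptive_rank_select(s)

    if cutoff > 0:
        low = (U[:, :cutoff] * s[:cutoff]) @ Vh[:cutoff]
        Cf = C - low
    else:
        Cf = C.copy()
    filtered = stack.with_frames(Cf.T.reshape(stack.shape))

    profile = _depth_noise_profile(np.abs(filtered.frames))

    n_keep = min(n_spatial_keep, U.shape[1])
    decomp = SVDDecomposition(
        singular_values=s,
        temporal_vectors=Vh,
        spatial_vectors=U[:, :n_keep].T.reshape(n_keep, stack.nz, stack.nx),
        cutoff=int(cutoff),
        noise_profile=profile,
    )
    return filtered, decomp


def _depth_noise_profile(magnitude: np.ndarray) -> NoiseProfile:
    """Per-depth noise gain from the lower quartile of |IQ|^2 over (x, t).

    The 25th percentile is insensitive to sparse bright bubbles, so on a
    clutter-filtered stack it tracks the noise floor; the profile is
    median-smoothed over 9 depth samples and normalized to unit mean.
    """
    q = np.percentile(magnitude ** 2, 25.0, axis=(0, 2))
    depth_rms = np.sqrt(np.clip(q, 1e-24, None))
    depth_rms = median_filter(depth_rms, size=9, mode="nearest")
    return NoiseProfile(depth_rms / depth_rms.mean())


def estimate_noise_profile(stack: IQStack) -> NoiseProfile:
    """Depth noise-gain profile of a (clutter-filtered) stack."""
    return _depth_noise_profile(np.abs(stack.frames))


def noise_equalize(stack: IQStack, profile: NoiseProfile | None = None) -> IQStack:
    """Divide the stack depth-wise by the noise gain profile."""
    if profile is None:
        profile = estimate_noise_profile(stack)
    gain = profile.gain
    if len(gain) != stack.nz:
        raise ValueError("profile length does not match stack depth")
    return stack.with_frames(stack.frames / gain[None, :, None])


def power_doppler(stack: IQStack) -> np.ndarray:
    """Pixelwise temporal mean of |IQ|^2 (non-negative image)."""
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    return np.mean(np.abs(stack.frames) ** 2, axis=0)


def estimate_heart_rate(stack: IQStack, band_bpm: tuple[float, float] = (240.0, 600.0)) -> float:
    """Heart rate (BPM) from the pulsatility of the power-Doppler signal.

    The per-frame spatial-mean power series is detrended and its periodogram
    peak located inside ``band_bpm``.  A peak sitting on the band edge or not
    rising clearly above the in-band floor raises :class:`NoPeakError`.
    """
    if stack.duration_s < 2.0:
        raise ValueError("need at least a 2 s record to resolve heart rate")
    series = np.mean(np.abs(stack.frames) ** 2, axis=(1, 2))
    if np.ptp(series) == 0:
        raise NoPeakError("flat power series")
    series = scipy.signal.detrend(series)
    freqs, power = scipy.signal.periodogram(series, fs=stack.frame_rate)
    lo, hi = band_bpm[0] / 60.0, band_bpm[1] / 60.0
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 3:
        raise ValueError("frequency resolution too coarse for the search band")
    p_band = power[band]
    f_band = freqs[band]
    k = int(np.argmax(p_band))
    if k in (0, len(p_band) - 1):
        raise NoPeakError("spectral maximum sits on the band edge (no interior peak)")
    if p_band[k] < 5.0 * np.median(p_band):
        raise NoPeakError("no periodogram peak above the in-band noise floor")
    return float(60.0 * f_band[k])
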