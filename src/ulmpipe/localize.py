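"""Per-frame microbubble localization.

Stages: empirical 2D-Gaussian PSF fitting, matching-pursuit separation of
overlapping echoes, cubic-spline upsampling to the super-resolved grid,
normalized cross-correlation against the PSF kernel, and sub-pixel centroid
refinement of the 8-connected regional maxima of the correlation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import curve_fit
from skimage.feature import match_template
from skimage.measure import label as cc_label
from skimage.morphology import local_maxima

from ulmpipe.core import DEFAULT_MAP_SPACING_UM

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PSFFitError(RuntimeError):
    """Gaussian fit failed on every supplied patch."""


@dataclass
class PSFModel:
    """Separable 2D Gaussian point-spread-function model (sigmas in um)."""

    sigma_z_um: float
    sigma_x_um: float
    amplitude: float = 1.0
    fit_residual_rms: float = 0.0
    n_patches_fit: int = 0

    def __post_init__(self) -> None:
        if self.sigma_z_um <= 0 or self.sigma_x_um <= 0:
            raise ValueError("PSF sigmas must be positive")

    @property
    def fwhm_um(self) -> float:
        return FWHM_PER_SIGMA * max(self.sigma_z_um, self.sigma_x_um)

    def kernel(self, spacing_um: float | tuple[float, float], n_sigma: float = 3.0) -> np.ndarray:
        """Rasterized kernel (peak 1 at the geometric centre, odd dimensions)."""
        dz, dx = (spacing_um, spacing_um) if np.isscalar(spacing_um) else spacing_um
        hz = max(1, int(np.ceil(n_sigma * self.sigma_z_um / dz)))
        hx = max(1, int(np.ceil(n_sigma * self.sigma_x_um / dx)))
        zz = np.arange(-hz, hz + 1) * dz / self.sigma_z_um
        xx = np.arange(-hx, hx + 1) * dx / self.sigma_x_um
        return np.exp(-0.5 * zz[:, None] ** 2) * np.exp(-0.5 * xx[None, :] ** 2)


def _gauss2d(coords, amp, z0, x0, sz, sx, off):
    z, x = coords
    return (amp * np.exp(-0.5 * ((z - z0) / sz) ** 2 - 0.5 * ((x - x0) / sx) ** 2) + off).ravel()


def fit_psf(patches: list[np.ndarray], spacing_um: float | tuple[float, float]) -> PSFModel:
    """Least-squares 2D Gaussian fit per patch; model sigmas are the medians.

    Patches that fail to fit (flat, divergent) are excluded; if every patch
    fails a :class:`PSFFitError` is raised.
    """
    if len(patches) < 3:
        raise ValueError("need at least 3 patches")
    dz, dx = (spacing_um, spacing_um) if np.isscalar(spacing_um) else spacing_um
    sigs_z, sigs_x, amps, resids = [], [], [], []
    for patch in patches:
        patch = np.asarray(patch, dtype=float)
        if np.ptp(patch) == 0:
            continue
        nz, nx = patch.shape
        zg, xg = np.meshgrid(np.arange(nz) * dz, np.arange(nx) * dx, indexing="ij")
        peak = np.unravel_index(np.argmax(patch), patch.shape)
        p0 = (patch.max() - patch.min(), peak[0] * dz, peak[1] * dx,
              nz * dz / 6, nx * dx / 6, patch.min())
        try:
            popt, _ = curve_fit(_gauss2d, (zg, xg), patch.ravel(), p0=p0, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        if popt[3] <= 0 or popt[4] <= 0 or not np.all(np.isfinite(popt)):
            continue
        sigs_z.append(abs(popt[3]))
        sigs_x.append(abs(popt[4]))
        amps.append(popt[0])
        resids.append(np.sqrt(np.mean((_gauss2d((zg, xg), *popt) - patch.ravel()) ** 2)))
    if not sigs_z:
        raise PSFFitError("Gaussian fit diverged on all patches")
    return PSFModel(
        sigma_z_um=float(np.median(sigs_z)),
        sigma_x_um=float(np.median(sigs_x)),
        amplitude=float(np.median(amps)),
        fit_residual_rms=float(np.mean(resids)),
        n_patches_fit=len(sigs_z),
    )


def matching_pursuit(frame: np.ndarray, kernel: np.ndarray, max_iters: int = 200,
                     stop_frac: float = 0.25) -> list[tuple[int, int, float]]:
    """Greedy peak-pick-and-subtract deconvolution on a magnitude frame.

    Iteratively finds the global maximum, records (z_px, x_px, amplitude) and
    subtracts the amplitude-scaled kernel; stops when the residual maximum
    drops below ``stop_frac`` times the initial maximum.  Raises on residual
    growth (non-convergence).
    """
    residual = np.asarray(frame, dtype=float).copy()
    initial = residual.max()
    if initial <= 0:
        return []
    hz, hx = kernel.shape[0] // 2, kernel.shape[1] // 2
    detections: list[tuple[int, int, float]] = []
    prev = np.inf
    for _ in range(max_iters):
        amp = residual.max()
        if amp < stop_frac * initial:
            break
        if amp > prev * 1.001:
            raise RuntimeError("matching pursuit diverged (residual growth)")
        prev = amp
        iz, ix = np.unravel_index(np.argmax(residual), residual.shape)
        detections.append((int(iz), int(ix), float(amp)))
        z0, z1 = max(0, iz - hz), min(residual.shape[0], iz + hz + 1)
        x0, x1 = max(0, ix - hx), min(residual.shape[1], ix + hx + 1)
        kz0, kx0 = z0 - (iz - hz), x0 - (ix - hx)
        residual[z0:z1, x0:x1] -= amp * kernel[kz0:kz0 + (z1 - z0), kx0:kx0 + (x1 - x0)]
    return detections


def separate_bubbles(frame: np.ndarray, psf: PSFModel,
                     spacing_um: float | tuple[float, float],
                     max_iters: int = 200, stop_frac: float = 0.25) -> list[np.ndarray]:
    """Split a magnitude frame into sparse component frames.

    Detections from matching pursuit are partitioned (round-robin over the
    existing components) such that no two detections in one component are
    closer than 2 x FWHM of the PSF; each component frame is the sum of the
    amplitude-scaled PSF kernels of its detections.
    """
    frame = np.asarray(frame, dtype=float)
    kernel = psf.kernel(spacing_um)
    detections = matching_pursuit(frame, kernel, max_iters=max_iters, stop_frac=stop_frac)
    if not detections:
        return []
    dz, dx = (spacing_um, spacing_um) if np.isscalar(spacing_um) else spacing_um
    min_sep_um = 2.0 * psf.fwhm_um
    components: list[list[tuple[int, int, float]]] = []
    start = 0
    for det in detections:
        placed = False
        for k in range(len(components)):
            comp = components[(start + k) % len(components)]
            ok = all(np.hypot((det[0] - d[0]) * dz, (det[1] - d[1]) * dx) >= min_sep_um
                     for d in comp)
            if ok:
                comp.append(det)
                start = (start + k + 1) % len(components)
                placed = True
                break
        if not placed:
            components.append([det])
    out = []
    hz, hx = kernel.shape[0] // 2, kernel.shape[1] // 2
    for comp in components:
        img = np.zeros_like(frame)
        for iz, ix, amp in comp:
            z0, z1 = max(0, iz - hz), min(img.shape[0], iz + hz + 1)
            x0, x1 = max(0, ix - hx), min(img.shape[1], ix + hx + 1)
            kz0, kx0 = z0 - (iz - hz), x0 - (ix - hx)
            img[z0:z1, x0:x1] += amp * kernel[kz0:kz0 + (z1 - z0), kx0:kx0 + (x1 - x0)]
        out.append(img)
    return out


def upsample_frame(frame: np.ndarray, in_spacing_um: float,
                   out_spacing_um: float = DEFAULT_MAP_SPACING_UM) -> np.ndarray:
    """Cubic-spline interpolation of a (real) frame onto a finer isotropic grid."""
    if in_spacing_um <= 0 or out_spacing_um <= 0:
        raise ValueError("spacings must be positive")
    if out_spacing_um > in_spacing_um:
        raise ValueError("output spacing must not exceed input spacing")
    frame = np.asarray(frame, dtype=float)
    if out_spacing_um == in_spacing_um:
        return frame.copy()
    nz, nx = frame.shape
    z = np.arange(nz) * in_spacing_um
    x = np.arange(nx) * in_spacing_um
    spline = RectBivariateSpline(z, x, frame, kx=3, ky=3, s=0)
    z_out = np.arange(0.0, z[-1] + out_spacing_um * 1e-9, out_spacing_um)
    x_out = np.arange(0.0, x[-1] + out_spacing_um * 1e-9, out_spacing_um)
    return spline(z_out, x_out)


def _quadratic_offset(cm: float, c0: float, cp: float) -> float:
    """Sub-pixel offset of a peak from 3-point quadratic interpolation."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def localize_frame(frame: np.ndarray, psf: PSFModel, spacing_um: float,
                   ncc_threshold: float = 0.6) -> list[tuple[float, float, float]]:
    """Detect sub-pixel bubble centroids on an upsampled magnitude frame.

    Zero-normalized cross-correlation against the PSF kernel; candidates are
    the 8-connected regional maxima with coefficient >= threshold; positions
    are refined to sub-pixel precision by quadratic interpolation of the
    correlation peak along each axis.  Returns ``(z_um, x_um, ncc)`` tuples.
    """
    frame = np.asarray(frame, dtype=float)
    kernel = psf.kernel(spacing_um)
    if kernel.shape[0] > frame.shape[0] or kernel.shape[1] > frame.shape[1]:
        raise ValueError("PSF kernel larger than frame")
    # valid-mode correlation avoids the unstable (zero-variance) borders of
    # the padded map; detections are therefore restricted to the interior
    ncc = match_template(frame, kernel, pad_input=False)
    ncc = np.where(np.isfinite(ncc), np.clip(ncc, -1.0, 1.0), 0.0)
    off_z, off_x = kernel.shape[0] // 2, kernel.shape[1] // 2
    maxima = local_maxima(ncc, connectivity=2, allow_borders=False)
    maxima &= ncc >= ncc_threshold
    if not maxima.any():
        return []
    labels = cc_label(maxima, connectivity=2)
    out: list[tuple[float, float, float]] = []
    for region in range(1, labels.max() + 1):
        zz, xx = np.nonzero(labels == region)
        best = int(np.argmax(ncc[zz, xx]))
        iz, ix = int(zz[best]), int(xx[best])
        wz = iz + _quadratic_offset(ncc[iz - 1, ix], ncc[iz, ix], ncc[iz + 1, ix])
        wx = ix + _quadratic_offset(ncc[iz, ix - 1], ncc[iz, ix], ncc[iz, ix + 1])
        out.append(((wz + off_z) * spacing_um, (wx + off_x) * spacing_um,
                    float(ncc[iz, ix])))
    return out


def localize_stack(magnitude_frames: np.ndarray, psf: PSFModel, in_spacing_um: float,
                   out_spacing_um: float = DEFAULT_MAP_SPACING_UM,
                   ncc_threshold: float = 0.6, separate: bool = False,
                   max_sep_iters: int = 200) -> pd.DataFrame:
    """Localize every frame of a magnitude stack.

    Returns a tidy table with columns ``frame, z_um, x_um, ncc``.
    """
    rows = []
    for f, frame in enumerate(magnitude_frames):
        subframes = (separate_bubbles(frame, psf, in_spacing_um, max_iters=max_sep_iters)
                     if separate else [frame])
        for sub in subframes:
            up = upsample_frame(sub, in_spacing_um, out_spacing_um)
            for z, x, c in localize_frame(up, psf, out_spacing_um, ncc_threshold):
                rows.append((f, z, x, c))
    return pd.DataFrame(rows, columns=["frame", "z_um", "x_um", "ncc"])
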