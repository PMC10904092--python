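"""Synthetic two-channel fluorescence section images.

The FITC channel carries vessel-wall-like rings (a dilated skeleton minus its
lumen), the second channel carries disk-shaped plaques.  A multiplicative
uneven-illumination field and plaque bleed-through into the FITC channel are
added to exercise the adaptive threshold and the morphometric exclusion rule.
Ground-truth positive-area fractions are recorded per channel per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk
from skimage.morphology import dilation

from ulmpipe.histo import HistoImage


def make_vessel_mask(shape: tuple[int, int], n_vessels: int = 12, seed: int = 0,
                     wall_px: int = 2, lumen_px: int = 3) -> np.ndarray:
    """Random piecewise-linear vessel skeletons dilated to wall-like rings."""
    rng = np.random.default_rng(seed)
    nz, nx = shape
    skel = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        p = np.array([rng.uniform(0, nz), rng.uniform(0, nx)])
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(rng.integers(3, 7)):
            length = rng.uniform(0.15, 0.4) * min(nz, nx)
            q = p + length * np.array([np.sin(ang), np.cos(ang)])
            n = int(np.ceil(length))
            zz = np.clip(np.linspace(p[0], q[0], n).astype(int), 0, nz - 1)
            xx = np.clip(np.linspace(p[1], q[1], n).astype(int), 0, nx - 1)
            skel[zz, xx] = True
            p = q
            ang += rng.uniform(-0.8, 0.8)
    inner = dilation(skel, np.ones((2 * lumen_px + 1,) * 2, dtype=bool))
    outer = dilation(inner, np.ones((2 * wall_px + 1,) * 2, dtype=bool))
    return outer & ~inner


def _illumination_field(shape: tuple[int, int], rng: np.random.Generator,
                        strength: float = 1.0) -> np.ndarray:
    nz, nx = shape
    z = np.linspace(-1, 1, nz)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    tilt = 1.0 + 0.25 * (rng.uniform(-1, 1) * z + rng.uniform(-1, 1) * x)
    vignette = 1.0 - 0.35 * (z ** 2 + x ** 2) / 2.0
    return 1.0 + strength * (tilt * vignette - 1.0)


def render_histology(plaque_fraction: dict[str, float], vessel_mask: np.ndarray,
                     region_masks: dict[str, np.ndarray], seed: int = 0, *,
                     illumination: bool = True, illumination_strength: float = 1.0,
                     bleed: float = 0.6,
                     plaque_radius_px: tuple[int, int] = (4, 12),
                     um_per_px: float = 2.0,
                     vessel_amp: float = 1.0, plaque_amp: float = 1.0,
                     background: float = 0.1,
                     noise_std: float = 0.02) -> tuple[HistoImage, pd.DataFrame]:
    """Render a two-channel section image with known positive-area truth.

    Parameters
    ----------
    plaque_fraction
        Target positive-area fraction (0..1) of the plaque channel per region.
    vessel_mask
        Boolean ground-truth FITC-positive mask (same shape as the regions).
    region_masks
        Named boolean ROI masks.

    Returns the image pair plus a tidy truth table with columns
    ``region, channel, truth_fraction_pct``.
    """
    for name, frac in plaque_fraction.items():
        if frac < 0:
            raise ValueError(f"plaque fraction for {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    shape = vessel_mask.shape
    plaques = np.zeros(shape, dtype=bool)
    for name, frac in plaque_fraction.items():
        region = region_masks[name]
        target = frac * region.sum()
        guard = 0
        while (plaques & region).sum() < target and guard < 10_000:
            guard += 1
            idx = np.argwhere(region)
            cz, cx = idx[rng.integers(len(idx))]
            r = rng.integers(plaque_radius_px[0], plaque_radius_px[1] + 1)
            rr, cc = disk((cz, cx), r, shape=shape)
            plaques[rr, cc] = True

    fitc = background + vessel_amp * vessel_mask + bleed * plaque_amp * plaques
    abeta = background + plaque_amp * plaques
    if illumination:
        field = _illumination_field(shape, rng, illumination_strength)
        fitc = fitc * field
        abeta = abeta * field
    fitc = np.clip(fitc + rng.normal(0, noise_std, shape), 0, None)
    abeta = np.clip(abeta + rng.normal(0, noise_std, shape), 0, None)

    rows = []
    for name, region in region_masks.items():
        denom = max(int(region.sum()), 1)
        rows.append((name, "fitc", 100.0 * (vessel_mask & region).sum() / denom))
        rows.append((name, "abeta", 100.0 * (plaques & region).sum() / denom))
    truth = pd.DataFrame(rows, columns=["region", "channel", "truth_fraction_pct"])
    return HistoImage(fitc=fitc, abeta=abeta, um_per_px=um_per_px), truth
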