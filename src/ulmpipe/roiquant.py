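"""ROI construction (Hobby spline) and regional / single-vessel metrics.

Metrics: vascularity (% of ROI pixels containing at least one accumulated
trajectory), median perfused-pixel velocity, sum-of-angles tortuosity (SOAM,
rad/mm), arteriole/venule splitting by flow direction against the cortical
surface normal, and cross-sectional velocity profiles with parabolic
(laminar-flow) fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.draw import polygon2mask

from ulmpipe.core import DEFAULT_MAP_SPACING_UM
from ulmpipe.maps import VascularMap
from ulmpipe.track import Track


class FitError(RuntimeError):
    """Degenerate or non-convergent profile fit."""


# ---------------------------------------------------------------------------
# Hobby's algorithm (closed paths, tension 1)
# ---------------------------------------------------------------------------

def _hobby_velocity(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Hobby's control-point velocity function (tension 1)."""
    num = 2.0 + np.sqrt(2.0) * (np.sin(theta) - np.sin(phi) / 16.0) \
        * (np.sin(phi) - np.sin(theta) / 16.0) * (np.cos(theta) - np.cos(phi))
    den = 3.0 * (1.0 + 0.5 * (np.sqrt(5.0) - 1.0) * np.cos(theta)
                 + 0.5 * (3.0 - np.sqrt(5.0)) * np.cos(phi))
    return num / den


def hobby_curve(vertices: np.ndarray, closed: bool = True,
                samples_per_segment: int = 30) -> np.ndarray:
    """Smooth closed curve through all control vertices via Hobby's algorithm.

    Tangent directions at the knots solve the cyclic tridiagonal
    mock-curvature system (all tensions 1); each span is then a cubic Bezier
    with Hobby's velocity formula for the control-point distances.  Returns a
    densely sampled ``(M, 2)`` polyline in (z, x) um whose last point repeats
    the first.
    """
    if not closed:
        raise NotImplementedError("only closed Hobby paths are supported")
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("need at least 3 (z, x) vertices")
    if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
        raise ValueError("duplicate adjacent vertices")
    if samples_per_segment < 20:
        raise ValueError("need >= 20 samples per segment")

    n = len(v)
    # complex plane: w = x + i z keeps angle conventions standard
    w = v[:, 1] + 1j * v[:, 0]
    chord = np.roll(w, -1) - w                      # chord i: knot i -> i+1
    d = np.abs(chord)
    gamma = np.angle(chord)
    # turning angle at knot i between chord i-1 and chord i, wrapped to (-pi, pi]
    psi = np.angle(np.exp(1j * (gamma - np.roll(gamma, 1))))

    # cyclic tridiagonal mock-curvature system for the departure angles theta
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(n):
        dm, dp = d[i - 1], d[i]
        A[i, (i - 1) % n] += 1.0 / dm
        A[i, i] += 2.0 / dm + 2.0 / dp
        A[i, (i + 1) % n] += 1.0 / dp
        rhs[i] = -2.0 * psi[i] / dm - psi[(i + 1) % n] / dp
    theta = np.linalg.solve(A, rhs)
    phi = -psi - theta                              # arrival angles (phi at knot i)

    pts = []
    ts = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
    for i in range(n):
        th = theta[i]
        ph = phi[(i + 1) % n]
        # the velocity function includes the 1/3 of the straight-line case
        rho = _hobby_velocity(th, ph)
        sigma = _hobby_velocity(ph, th)
        c1 = w[i] + rho * d[i] * np.exp(1j * (gamma[i] + th))
        c2 = w[(i + 1) % n] - sigma * d[i] * np.exp(1j * (gamma[i] - ph))
        p0, p3 = w[i], w[(i + 1) % n]
        b = ((1 - ts) ** 3 * p0 + 3 * (1 - ts) ** 2 * ts * c1
             + 3 * (1 - ts) * ts ** 2 * c2 + ts ** 3 * p3)
        pts.append(b)
    curve = np.concatenate(pts + [w[:1]])
    return np.stack([curve.imag, curve.real], axis=1)


def rasterize_roi(curve: np.ndarray, shape: tuple[int, int],
                  spacing_um: float = DEFAULT_MAP_SPACING_UM) -> np.ndarray:
    """Even-odd fill of a closed curve onto pixel centres."""
    curve = np.asarray(curve, dtype=float)
    if not np.allclose(curve[0], curve[-1], atol=1e-6):
        raise ValueError("curve must be closed (last point == first point)")
    return polygon2mask(shape, curve / spacing_um)


@dataclass
class ROIPolygon:
    """Hobby-interpolated closed region with its raster mask."""

    vertices_um: np.ndarray
    label: str = "custom"
    surface_normal: tuple[float, float] | None = None   # (z, x) unit, into brain
    curve: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float)
        self.curve = hobby_curve(self.vertices_um, closed=True)

    def mask(self, shape: tuple[int, int],
             spacing_um: float = DEFAULT_MAP_SPACING_UM) -> np.ndarray:
        m = rasterize_roi(self.curve, shape, spacing_um)
        if not m.any():
            raise ValueError(f"ROI {self.label!r} rasterizes to an empty mask")
        return m


# ---------------------------------------------------------------------------
# Regional metrics
# ---------------------------------------------------------------------------

def vascularity(vmap: VascularMap, mask: np.ndarray) -> float:
    """Percent of ROI pixels containing at least one trajectory."""
    if mask.sum() == 0:
        raise ValueError("empty ROI mask")
    return float(100.0 * (vmap.perfused & mask).sum() / mask.sum())


def median_velocity(vmap: VascularMap, mask: np.ndarray) -> float:
    """Median of the velocity raster over perfused ROI pixels (mm/s)."""
    vals = vmap.velocity[mask & vmap.perfused]
    if vals.size == 0:
        raise ValueError("no perfused pixels in the ROI")
    return float(np.median(vals))


def soam(track) -> float:
    """Sum-of-angles tortuosity: total turning angle / path length (rad/mm).

    Accepts a :class:`~ulmpipe.track.Track` or an ``(N, 2)`` array of um
    positions.  Zero-length steps are dropped with a warning.
    """
    pts = track.positions_um if isinstance(track, Track) else np.asarray(track, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 centroids")
    steps = np.diff(pts, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    if np.any(lens == 0):
        warnings.warn("dropping zero-length steps")
        steps = steps[lens > 0]
        lens = lens[lens > 0]
    if len(steps) < 2:
        raise ValueError("degenerate track (fewer than 2 non-zero steps)")
    u = steps / lens[:, None]
    cosang = np.clip((u[:-1] * u[1:]).sum(axis=1), -1.0, 1.0)
    total_angle = np.sum(np.arccos(cosang))
    path_mm = lens.sum() / 1e3
    return float(total_angle / path_mm)


def track_in_roi(track: Track, mask: np.ndarray,
                 spacing_um: float = DEFAULT_MAP_SPACING_UM) -> bool:
    """Majority-of-centroids inclusion rule."""
    idx = np.round(track.positions_um / spacing_um).astype(int)
    nz, nx = mask.shape
    inside = ((idx[:, 0] >= 0) & (idx[:, 0] < nz) & (idx[:, 1] >= 0) & (idx[:, 1] < nx))
    hits = mask[idx[inside, 0], idx[inside, 1]].sum()
    return hits > len(track) / 2.0


def roi_soam(tracks: list[Track], mask: np.ndarray,
             spacing_um: float = DEFAULT_MAP_SPACING_UM) -> float:
    """Mean SOAM over tracks whose majority of centroids lie in the ROI."""
    vals = [soam(t) for t in tracks if len(t) >= 3 and track_in_roi(t, mask, spacing_um)]
    if not vals:
        raise ValueError("no eligible tracks in the ROI")
    return float(np.mean(vals))


def split_arteriole_venule(tracks: list[Track], surface_normal: tuple[float, float],
                           mask: np.ndarray | None = None,
                           spacing_um: float = DEFAULT_MAP_SPACING_UM,
                           ) -> tuple[list[Track], list[Track], list[Track]]:
    """Classify tracks by mean flow direction against the inward surface normal.

    Flow into the cortex (positive dot product with ``surface_normal``) is
    arteriole, flow outward is venule; zero mean vectors are excluded but
    counted.  Returns ``(arterioles, venules, excluded)``.
    """
    nvec = np.asarray(surface_normal, dtype=float)
    nvec = nvec / np.linalg.norm(nvec)
    art, ven, excl = [], [], []
    for t in tracks:
        if mask is not None and not track_in_roi(t, mask, spacing_um):
            continue
        v = t.mean_velocity_mms
        dot = float(v @ nvec)
        if dot > 0:
            art.append(t)
        elif dot < 0:
            ven.append(t)
        else:
            excl.append(t)
    return art, ven, excl


# ---------------------------------------------------------------------------
# Single-vessel profiles
# ---------------------------------------------------------------------------

@dataclass
class VesselProfile:
    """Binned crossing speeds along a manually placed cross-section segment."""

    segment_um: np.ndarray          # (2, 2) endpoints
    bin_centers_um: np.ndarray
    peak_mms: np.ndarray            # per-bin max crossing speed (nan if empty)
    mean_mms: np.ndarray
    counts: np.ndarray

    @property
    def n_crossings(self) -> int:
        return int(self.counts.sum())


@dataclass
class ParabolaFit:
    v_peak_mms: float
    center_um: float
    radius_um: float
    residual_rms: float


def _segment_intersection(p, q, a, b):
    """Intersection of segments p->q and a->b; returns (s, t) params or None."""
    r = q - p
    s_ = b - a
    denom = r[0] * s_[1] - r[1] * s_[0]
    if denom == 0:
        return None
    dp = a - p
    t = (dp[0] * s_[1] - dp[1] * s_[0]) / denom
    u = (dp[0] * r[1] - dp[1] * r[0]) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return t, u
    return None


def vessel_profile(tracks: list[Track], segment_um: np.ndarray,
                   bin_um: float = DEFAULT_MAP_SPACING_UM) -> VesselProfile:
    """Collect speeds of every track step crossing the segment, binned by
    lateral offset along the segment."""
    seg = np.asarray(segment_um, dtype=float)
    a, b = seg[0], seg[1]
    seg_len = np.linalg.norm(b - a)
    if seg_len == 0:
        raise ValueError("degenerate segment")
    offsets, speeds = [], []
    for t in tracks:
        pos = t.positions_um
        sp = t.step_speeds_mms
        for s in range(len(pos) - 1):
            hit = _segment_intersection(pos[s], pos[s + 1], a, b)
            if hit is not None:
                offsets.append(hit[1] * seg_len)
                speeds.append(sp[s])
    if not offsets:
        raise ValueError("no track crosses the segment")
    offsets = np.asarray(offsets)
    speeds = np.asarray(speeds)
    edges = np.arange(0.0, seg_len + bin_um, bin_um)
    idx = np.clip(np.digitize(offsets, edges) - 1, 0, len(edges) - 2)
    nbins = len(edges) - 1
    peak = np.full(nbins, np.nan)
    mean = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for k in range(nbins):
        sel = idx == k
        counts[k] = sel.sum()
        if counts[k]:
            peak[k] = speeds[sel].max()
            mean[k] = speeds[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VesselProfile(seg, centers, peak, mean, counts)


def fit_parabola(profile: VesselProfile) -> ParabolaFit:
    """Least-squares fit of v(r) = v_peak (1 - ((r - c)/R)^2) to per-bin maxima."""
    sel = profile.counts > 0
    r = profile.bin_centers_um[sel]
    v = profile.peak_mms[sel]
    if sel.sum() < 3:
        raise ValueError("need at least 3 populated bins")
    span = r.max() - r.min()
    if span == 0 or np.ptp(v) < 1e-9 * max(abs(v).max(), 1.0):
        raise FitError("flat profile (radius unbounded)")

    def model(rr, vp, c, R):
        return vp * (1.0 - ((rr - c) / R) ** 2)

    p0 = (v.max(), r[np.argmax(v)], max(span / 2.0, 1e-3))
    try:
        popt, _ = curve_fit(model, r, v, p0=p0,
                            bounds=([0.0, r.min() - span, 1e-6],
                                    [np.inf, r.max() + span, np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"parabola fit did not converge: {exc}") from exc
    vp, c, R = popt
    if R > 10.0 * max(span, 1.0):
        raise FitError("fitted radius unbounded (flat profile)")
    rms = float(np.sqrt(np.mean((model(r, *popt) - v) ** 2)))
    return ParabolaFit(float(vp), float(c), float(R), rms)


# ---------------------------------------------------------------------------
# Metric table assembly
# ---------------------------------------------------------------------------

def roi_metrics(vmap: VascularMap, tracks: list[Track], roi: ROIPolygon,
                spacing_um: float = DEFAULT_MAP_SPACING_UM) -> pd.DataFrame:
    """One row per subset (all / arteriole / venule) of the regional metrics."""
    mask = roi.mask(vmap.shape, spacing_um)
    rows = []

    def metrics_for(subset_tracks: list[Track], subset: str):
        sub_map = vmap if subset == "all" else None
        if sub_map is None:
            from ulmpipe.maps import accumulate
            sub_map = accumulate(subset_tracks, vmap.shape, spacing_um)
        try:
            med = median_velocity(sub_map, mask)
        except ValueError:
            med = np.nan
        try:
            tort = roi_soam(subset_tracks, mask, spacing_um)
        except ValueError:
            tort = np.nan
        rows.append({
            "region": roi.label, "subset": subset,
            "vascularity_pct": vascularity(sub_map, mask),
            "median_velocity_mms": med, "soam": tort,
            "track_count": len(subset_tracks),
        })

    in_roi = [t for t in tracks if track_in_roi(t, mask, spacing_um)]
    metrics_for(in_roi, "all")
    if roi.surface_normal is not None:
        art, ven, _ = split_arteriole_venule(in_roi, roi.surface_normal)
        metrics_for(art, "arteriole")
        metrics_for(ven, "venule")
    return pd.DataFrame(rows)
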