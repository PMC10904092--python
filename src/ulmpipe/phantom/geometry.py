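"""Tube-vessel geometries for the flow phantom.

A vessel is a polyline centerline in the imaging plane together with a tube
radius and a Poiseuille peak velocity.  The ordering of the centerline points
defines the flow direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default field of view: 128 px at the 19.712 um native pitch
DEFAULT_FOV_UM = (128 * 19.712, 128 * 19.712)

PRESETS = ("straight", "sinusoid", "semicircle", "bifurcation", "cortical_column")


@dataclass
class Vessel:
    """One tube vessel.

    ``centerline`` is an ``(N, 2)`` array of (z, x) points in um, ordered in
    the direction of flow.  ``radius_um`` and ``peak_velocity_mms`` define the
    laminar (Poiseuille) velocity profile v(r) = v_peak * (1 - r^2/R^2).
    """

    centerline: np.ndarray
    radius_um: float
    peak_velocity_mms: float
    label: str = ""

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2 or len(self.centerline) < 2:
            raise ValueError("centerline must be an (N>=2, 2) array of (z, x) um")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.peak_velocity_mms <= 0:
            raise ValueError("peak velocity must be positive")
        seg = np.diff(self.centerline, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(self._seg_len == 0):
            raise ValueError("centerline contains duplicate consecutive points")
        self._cum_len = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self._seg_dir = seg / self._seg_len[:, None]

    @property
    def length_um(self) -> float:
        return float(self._cum_len[-1])

    @property
    def flow_direction(self) -> np.ndarray:
        """Unit tangent of the first segment (z, x)."""
        return self._seg_dir[0].copy()

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Centerline point(s) at arc length ``s`` um (clipped to the vessel)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_um)
        idx = np.clip(np.searchsorted(self._cum_len, s, side="right") - 1, 0, len(self._seg_len) - 1)
        frac = s - self._cum_len[idx]
        return self.centerline[idx] + self._seg_dir[idx] * frac[:, None]

    def tangent_at(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_um)
        idx = np.clip(np.searchsorted(self._cum_len, s, side="right") - 1, 0, len(self._seg_len) - 1)
        return self._seg_dir[idx]

    def normal_at(self, s: np.ndarray) -> np.ndarray:
        """In-plane unit normal (tangent rotated +90 degrees)."""
        t = self.tangent_at(s)
        return np.stack([t[:, 1], -t[:, 0]], axis=1)


@dataclass
class VesselGeometry:
    """A collection of vessels sharing one field of view."""

    vessels: list[Vessel]
    fov_um: tuple[float, float] = DEFAULT_FOV_UM

    def __post_init__(self) -> None:
        if not self.vessels:
            raise ValueError("geometry must contain at least one vessel")
        fz, fx = self.fov_um
        for v in self.vessels:
            cl = v.centerline
            if (cl[:, 0].min() < 0 or cl[:, 0].max() > fz
                    or cl[:, 1].min() < 0 or cl[:, 1].max() > fx):
                raise ValueError(f"vessel {v.label!r} centerline leaves the field of view")

    def __len__(self) -> int:
        return len(self.vessels)

    def __iter__(self):
        return iter(self.vessels)


def make_vessel_tree(preset: str, *, fov_um: tuple[float, float] = DEFAULT_FOV_UM,
                     radius_um: float = 25.0, peak_velocity_mms: float = 8.0,
                     **params) -> VesselGeometry:
    """Build a named preset vessel geometry.

    Presets
    -------
    straight
        One horizontal tube (params: ``depth_um``, ``length_um``, ``x0_um``).
    sinusoid
        z = depth + amp * sin(2 pi x / period) (params: ``amplitude_um``,
        ``period_um``).
    semicircle
        Half-circle arc (params: ``r_curve_um``, ``n_points``).
    bifurcation
        Parent tube splitting into two daughters at a junction point.
    cortical_column
        One descending plus one ascending vertical vessel (for the
        arteriole/venule direction-splitting tests).
    """
    fz, fx = fov_um
    if preset == "straight":
        depth = params.get("depth_um", fz / 2)
        length = params.get("length_um", 0.8 * fx)
        x0 = params.get("x0_um", (fx - length) / 2)
        n = params.get("n_points", 64)
        xs = np.linspace(x0, x0 + length, n)
        cl = np.stack([np.full(n, depth), xs], axis=1)
        vessels = [Vessel(cl, radius_um, peak_velocity_mms, "straight")]
    elif preset == "sinusoid":
        depth = params.get("depth_um", fz / 2)
        amp = params.get("amplitude_um", 150.0)
        period = params.get("period_um", 800.0)
        length = params.get("length_um", 0.8 * fx)
        x0 = params.get("x0_um", (fx - length) / 2)
        n = params.get("n_points", 256)
        xs = np.linspace(x0, x0 + length, n)
        zs = depth + amp * np.sin(2 * np.pi * (xs - x0) / period)
        vessels = [Vessel(np.stack([zs, xs], axis=1), radius_um, peak_velocity_mms, "sinusoid")]
    elif preset == "semicircle":
        r = params.get("r_curve_um", 200.0)
        cz = params.get("center_z_um", fz / 2)
        cx = params.get("center_x_um", fx / 2)
        n = params.get("n_points", 256)
        theta = np.linspace(0.0, np.pi, n)
        cl = np.stack([cz - r * np.sin(theta), cx - r * np.cos(theta)], axis=1)
        vessels = [Vessel(cl, radius_um, peak_velocity_mms, "semicircle")]
    elif preset == "bifurcation":
        jz = params.get("junction_z_um", fz / 2)
        jx = params.get("junction_x_um", fx / 2)
        length = params.get("length_um", 0.3 * fx)
        half_angle = np.deg2rad(params.get("half_angle_deg", 30.0))
        parent = np.stack([np.full(32, jz), np.linspace(jx - length, jx, 32)], axis=1)
        t = np.linspace(0, length, 32)[:, None]
        up = np.array([jz, jx]) + t * np.array([-np.sin(half_angle), np.cos(half_angle)])
        dn = np.array([jz, jx]) + t * np.array([np.sin(half_angle), np.cos(half_angle)])
        vessels = [
            Vessel(parent, radius_um, peak_velocity_mms, "parent"),
            Vessel(up, radius_um * 0.8, peak_velocity_mms * 0.8, "daughter_up"),
            Vessel(dn, radius_um * 0.8, peak_velocity_mms * 0.8, "daughter_down"),
        ]
    elif preset == "cortical_column":
        z0 = params.get("z_top_um", 0.05 * fz)
        z1 = params.get("z_bottom_um", 0.95 * fz)
        xa = params.get("x_descending_um", 0.4 * fx)
        xv = params.get("x_ascending_um", 0.6 * fx)
        n = params.get("n_points", 64)
        desc = np.stack([np.linspace(z0, z1, n), np.full(n, xa)], axis=1)
        asc = np.stack([np.linspace(z1, z0, n), np.full(n, xv)], axis=1)
        vessels = [
            Vessel(desc, radius_um, peak_velocity_mms, "descending"),
            Vessel(asc, radius_um, peak_velocity_mms, "ascending"),
        ]
    else:
        raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    return VesselGeometry(vessels, fov_um)
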