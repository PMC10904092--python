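"""Bubble kinematics: advect point scatterers through tube vessels.

Bubbles are seeded uniformly over the circular cross-section (radial offset
r = R * sqrt(u)) and advected at the local laminar speed
v(r) = v_peak * (1 - r^2 / R^2), which makes the bubble-population mean speed
exactly v_peak / 2.  The radial position is frozen for a bubble's lifetime so
the true speed of each track is a scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ulmpipe.phantom.geometry import VesselGeometry

TRACK_COLUMNS = ["bubble_id", "vessel_id", "frame", "z_um", "x_um", "speed_mms"]


@dataclass
class GroundTruthTracks:
    """Per-bubble position sequences with the true scalar speed.

    ``df`` has columns ``bubble_id, vessel_id, frame, z_um, x_um, speed_mms``
    sorted by (bubble_id, frame); frames are strictly consecutive per bubble.
    """

    df: pd.DataFrame
    frame_rate: float

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")

    @property
    def n_bubbles(self) -> int:
        return self.df["bubble_id"].nunique()

    def bubble_speeds(self) -> pd.Series:
        return self.df.groupby("bubble_id")["speed_mms"].first()

    def positions_by_frame(self, frame: int) -> np.ndarray:
        sub = self.df[self.df["frame"] == frame]
        return sub[["z_um", "x_um"]].to_numpy()

    def to_tracks(self) -> list:
        """Convert to :class:`ulmpipe.track.Track` objects (ground-truth oracle)."""
        from ulmpipe.track import Track

        out = []
        for _, g in self.df.groupby("bubble_id"):
            if len(g) < 2:
                continue
            out.append(Track(g["frame"].to_numpy(int), g[["z_um", "x_um"]].to_numpy(float),
                             self.frame_rate))
        return out

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, frame_rate: float) -> "GroundTruthTracks":
        return cls(pd.read_csv(path), frame_rate)


def simulate_tracks(geom: VesselGeometry, duration_s: float, frame_rate: float,
                    bubble_rate: float, seed: int = 0) -> GroundTruthTracks:
    """Simulate bubble passages through ``geom``.

    ``bubble_rate`` is the expected number of bubbles entering the whole
    geometry per frame; it is split across vessels proportionally to their
    volumetric flux (R^2 * v_peak).  Entry times extend far enough into the
    past that the tube is in steady state at frame 0.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if bubble_rate <= 0:
        raise ValueError("bubble rate must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    flux = np.array([v.radius_um ** 2 * v.peak_velocity_mms for v in geom.vessels])
    rates = bubble_rate * flux / flux.sum()

    rows = []
    bubble_id = 0
    for vid, (vessel, rate) in enumerate(zip(geom.vessels, rates)):
        vmax = vessel.peak_velocity_mms
        # entries uniform over the record (keeps speed sampling unbiased and
        # makes #entering bubbles == #tracks); every entry lands on >= 1 frame
        n_bubbles = rng.poisson(rate * n_frames)
        t_entry = rng.uniform(0.0, (n_frames - 1) / frame_rate, size=n_bubbles)
        r = vessel.radius_um * np.sqrt(rng.uniform(size=n_bubbles))
        phi = rng.uniform(0, 2 * np.pi, size=n_bubbles)
        offset = r * np.cos(phi)  # in-plane projection of the radial offset
        speed = vmax * (1.0 - (r / vessel.radius_um) ** 2)  # mm/s, frozen

        for b in range(n_bubbles):
            v_um_per_frame = speed[b] * 1e3 / frame_rate
            if v_um_per_frame <= 0:
                continue
            # frames during which the bubble is inside the tube
            f0 = max(0, int(np.ceil(t_entry[b] * frame_rate)))
            f1 = min(n_frames - 1,
                     int(np.floor((t_entry[b] + vessel.length_um / (speed[b] * 1e3)) * frame_rate)))
            if f1 < f0:
                continue
            frames = np.arange(f0, f1 + 1)
            s = (frames / frame_rate - t_entry[b]) * speed[b] * 1e3
            pos = vessel.point_at(s) + vessel.normal_at(s) * offset[b]
            for f, (z, x) in zip(frames, pos):
                rows.append((bubble_id, vid, int(f), z, x, speed[b]))
            bubble_id += 1

    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if len(df):
        df = df.sort_values(["bubble_id", "frame"]).reset_index(drop=True)
    return GroundTruthTracks(df, frame_rate)
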