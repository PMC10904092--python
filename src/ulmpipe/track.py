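"""Frame-to-frame centroid linking into trajectories.

Linking is a gated linear assignment problem (LAP): within each consecutive
frame pair a one-to-one assignment minimizes the total squared displacement
among candidate pairs inside the gate, with non-assignment (track birth or
death) costed at gate^2.  There is no gap closing: a single-frame dropout
terminates a track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

DEFAULT_GATE_UM = 30.0   # 1.5 x (20 mm/s expected max) / 1 kHz
DEFAULT_MIN_LEN = 10     # frames

_FORBIDDEN = 1e18


@dataclass
class Track:
    """An ordered sequence of centroids on strictly consecutive frames."""

    frames: np.ndarray            # (N,) int
    positions_um: np.ndarray      # (N, 2) (z, x)
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.frames) != len(self.positions_um):
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def steps_um(self) -> np.ndarray:
        return np.diff(self.positions_um, axis=0)

    @property
    def velocities_mms(self) -> np.ndarray:
        """Per-step velocity vectors (vz, vx) in mm/s."""
        return self.steps_um * self.frame_rate / 1e3

    @property
    def step_speeds_mms(self) -> np.ndarray:
        v = self.velocities_mms
        return np.hypot(v[:, 0], v[:, 1])

    @property
    def mean_speed_mms(self) -> float:
        return track_speed(self, self.frame_rate)

    @property
    def mean_velocity_mms(self) -> np.ndarray:
        if len(self) < 2:
            raise ValueError("velocity undefined for a single-point track")
        return self.velocities_mms.mean(axis=0)


def track_speed(track: Track, frame_rate: float | None = None) -> float:
    """Mean per-step speed (Euclidean step length x frame rate / 1000) in mm/s."""
    if len(track) < 2:
        raise ValueError("speed undefined for a single-point track")
    rate = frame_rate if frame_rate is not None else track.frame_rate
    steps = np.diff(track.positions_um, axis=0)
    return float(np.mean(np.hypot(steps[:, 0], steps[:, 1])) * rate / 1e3)


def link_frames(locs_t: np.ndarray, locs_t1: np.ndarray,
                gate_um: float = DEFAULT_GATE_UM) -> list[tuple[int, int]]:
    """Gated one-to-one assignment between two frames of localizations.

    Returns index pairs ``(i, j)`` with ``locs_t[i]`` matched to
    ``locs_t1[j]``; unmatched points on either side start or terminate tracks.
    """
    if gate_um <= 0:
        raise ValueError("gate must be positive")
    a = np.asarray(locs_t, dtype=float).reshape(-1, 2)
    b = np.asarray(locs_t1, dtype=float).reshape(-1, 2)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    gate2 = gate_um ** 2
    link = np.where(d2 <= gate2, d2, _FORBIDDEN)
    death = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(death, gate2)
    birth = np.full((m, m), _FORBIDDEN)
    np.fill_diagonal(birth, gate2)
    # layout: rows = old points + birth dummies, cols = new points + death
    # dummies; the lower-right (dummy-dummy) block is free
    cost = np.block([[link, death], [birth, np.zeros((m, n))]])
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
             if r < n and c < m and d2[r, c] <= gate2]
    return pairs


def build_tracks(localizations: pd.DataFrame, frame_rate: float,
                 gate_um: float = DEFAULT_GATE_UM,
                 min_len: int = DEFAULT_MIN_LEN) -> list[Track]:
    """Assemble tracks by repeated frame-pair linking.

    ``localizations`` needs columns ``frame, z_um, x_um`` (sorted or not).
    Tracks shorter than ``min_len`` frames are discarded.
    """
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    if len(localizations) == 0:
        return []
    df = localizations.sort_values("frame")
    by_frame = {int(f): g[["z_um", "x_um"]].to_numpy(float)
                for f, g in df.groupby("frame")}
    f_min, f_max = min(by_frame), max(by_frame)

    finished: list[tuple[list[int], list[np.ndarray]]] = []
    active: list[tuple[list[int], list[np.ndarray]]] = []
    for f in range(f_min, f_max + 1):
        locs = by_frame.get(f, np.empty((0, 2)))
        if active:
            last = np.array([t[1][-1] for t in active])
            pairs = link_frames(last, locs, gate_um)
            matched_tracks = {i for i, _ in pairs}
            matched_locs = {j for _, j in pairs}
            for i, j in pairs:
                active[i][0].append(f)
                active[i][1].append(locs[j])
            finished.extend(t for k, t in enumerate(active) if k not in matched_tracks)
            active = [t for k, t in enumerate(active) if k in matched_tracks]
        else:
            matched_locs = set()
        for j in range(len(locs)):
            if j not in matched_locs:
                active.append(([f], [locs[j]]))
    finished.extend(active)

    return [Track(np.array(frames), np.array(pos), frame_rate)
            for frames, pos in finished if len(frames) >= min_len]


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tidy table: track_id, frame, z_um, x_um, vz_mms, vx_mms, speed_mms."""
    rows = []
    for tid, t in enumerate(tracks):
        v = t.velocities_mms
        for k in range(len(t)):
            kv = min(k, len(v) - 1) if len(v) else None
            vz, vx = (v[kv] if kv is not None else (np.nan, np.nan))
            rows.append((tid, int(t.frames[k]), t.positions_um[k, 0], t.positions_um[k, 1],
                         vz, vx, np.hypot(vz, vx)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "z_um", "x_um",
                                       "vz_mms", "vx_mms", "speed_mms"])


def tracks_from_frame(df: pd.DataFrame, frame_rate: float) -> list[Track]:
    return [Track(g["frame"].to_numpy(int), g[["z_um", "x_um"]].to_numpy(float), frame_rate)
            for _, g in df.groupby("track_id")]
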