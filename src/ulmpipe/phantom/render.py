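"""Render ground-truth bubble tracks into complex IQ frame stacks.

Each bubble contributes a 2D Gaussian echo with a per-bubble log-normal
amplitude and random phase; tissue clutter is an exactly rank-K sum of smooth
spatial patterns times slow temporal envelopes; additive circular complex
noise follows a configurable depth-gain profile.  Clutter and bubble
amplitudes can be modulated at a cardiac frequency.

Per-bubble draws are keyed on ``(seed, bubble_id)`` so rendering a subset of
the tracks reproduces exactly the same echoes (linear superposition holds up
to the shared clutter/noise background).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from ulmpipe.core import IQStack
from ulmpipe.phantom.tracks import GroundTruthTracks

_CLUTTER_KEY = 1_000_003
_NOISE_KEY = 1_000_033


@dataclass
class PhantomConfig:
    """Rendering parameters for the IQ phantom."""

    bubble_rate: float = 2.0            # bubbles/frame (used by pipeline front-end)
    psf_sigma_um: tuple[float, float] = (40.0, 60.0)   # (axial, lateral)
    amp_sigma_log: float = 0.3          # log-normal sigma of bubble amplitudes
    clutter_rank: int = 0
    clutter_amp: float = 0.0
    clutter_component_decay: float = 0.6   # amplitude ratio between components
    clutter_spatial_sigma_px: float = 12.0
    clutter_temporal_sigma_frames: float = 80.0
    noise_floor: float = 0.0            # noise std at the shallowest depth
    noise_depth_slope: float = 1.0      # g(z) = 1 + slope * z / z_max
    cardiac_freq_hz: float = 7.0        # 420 BPM
    cardiac_mod_depth: float = 0.0      # in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clutter_rank < 0:
            raise ValueError("clutter rank must be >= 0")
        if not (0.0 <= self.cardiac_mod_depth < 1.0):
            raise ValueError("cardiac modulation depth must be in [0, 1)")
        if self.psf_sigma_um[0] <= 0 or self.psf_sigma_um[1] <= 0:
            raise ValueError("PSF sigmas must be positive")

    def noise_depth_gain(self, nz: int) -> np.ndarray:
        """Per-depth noise gain g(z), unit gain at z=0."""
        z = np.arange(nz, dtype=float)
        return 1.0 + self.noise_depth_slope * z / max(nz - 1, 1)

    def to_dict(self) -> dict:
        return asdict(self)


def _bubble_draw(seed: int, bubble_id: int, amp_sigma_log: float) -> tuple[float, complex]:
    """Deterministic per-bubble amplitude and phase, independent of subset."""
    rng = np.random.default_rng([seed, int(bubble_id)])
    amp = float(np.exp(rng.normal(0.0, amp_sigma_log)))
    phase = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi))
    return amp, phase


def _add_gaussian(frame: np.ndarray, z_px: float, x_px: float, amp: complex,
                  sig_z_px: float, sig_x_px: float, n_sigma: float = 4.0) -> None:
    nz, nx = frame.shape
    z0 = max(0, int(np.floor(z_px - n_sigma * sig_z_px)))
    z1 = min(nz, int(np.ceil(z_px + n_sigma * sig_z_px)) + 1)
    x0 = max(0, int(np.floor(x_px - n_sigma * sig_x_px)))
    x1 = min(nx, int(np.ceil(x_px + n_sigma * sig_x_px)) + 1)
    if z1 <= z0 or x1 <= x0:
        return
    zz = (np.arange(z0, z1) - z_px) / sig_z_px
    xx = (np.arange(x0, x1) - x_px) / sig_x_px
    frame[z0:z1, x0:x1] += amp * np.exp(-0.5 * zz[:, None] ** 2) * np.exp(-0.5 * xx[None, :] ** 2)


def render_clutter(cfg: PhantomConfig, shape: tuple[int, int], n_frames: int,
                   frame_rate: float) -> np.ndarray:
    """Exactly rank-``cfg.clutter_rank`` smooth clutter, (n_frames, nz, nx)."""
    nz, nx = shape
    out = np.zeros((n_frames, nz, nx), dtype=np.complex128)
    if cfg.clutter_rank == 0 or cfg.clutter_amp == 0.0:
        return out
    rng = np.random.default_rng([cfg.seed, _CLUTTER_KEY])
    t = np.arange(n_frames) / frame_rate
    mod = 1.0 + cfg.cardiac_mod_depth * np.sin(2 * np.pi * cfg.cardiac_freq_hz * t)
    for k in range(cfg.clutter_rank):
        spatial = gaussian_filter(rng.normal(size=(nz, nx)), cfg.clutter_spatial_sigma_px)
        spatial /= np.abs(spatial).max() + 1e-30
        # distinct slow envelopes so the clutter Casorati rank really is K:
        # a DC-dominated lead component plus slow oscillations for the rest
        # keep envelope (and envelope-product) spectral content well below
        # the cardiac search band
        f_k = rng.uniform(0.2, 1.2)
        phase_t = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * f_k * t + phase_t)
        smooth = gaussian_filter1d(rng.normal(size=n_frames), cfg.clutter_temporal_sigma_frames)
        smooth /= np.std(smooth) + 1e-30
        if k == 0:
            temporal = 1.0 + 0.3 * osc + 0.1 * smooth
        else:
            temporal = osc + 0.2 * smooth
        phase = np.exp(1j * rng.uniform(0, 2 * np.pi))
        amp = cfg.clutter_amp * (cfg.clutter_component_decay ** k)
        out += amp * phase * (temporal * mod)[:, None, None] * spatial[None, :, :]
    return out


def render_noise(cfg: PhantomConfig, shape: tuple[int, int], n_frames: int) -> np.ndarray:
    nz, nx = shape
    if cfg.noise_floor == 0.0:
        return np.zeros((n_frames, nz, nx), dtype=np.complex128)
    rng = np.random.default_rng([cfg.seed, _NOISE_KEY])
    gain = cfg.noise_depth_gain(nz)
    noise = (rng.standard_normal((n_frames, nz, nx))
             + 1j * rng.standard_normal((n_frames, nz, nx))) / np.sqrt(2.0)
    return cfg.noise_floor * gain[None, :, None] * noise


def render_iq(tracks: GroundTruthTracks, cfg: PhantomConfig,
              shape: tuple[int, int] = (128, 128),
              pixel_spacing_um: tuple[float, float] = (19.712, 19.712),
              frame_rate: float | None = None,
              n_frames: int | None = None) -> IQStack:
    """Superimpose bubble echoes, clutter and noise into an IQ stack."""
    frame_rate = frame_rate if frame_rate is not None else tracks.frame_rate
    df = tracks.df
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    nz, nx = shape
    dz, dx = pixel_spacing_um
    sig_z_px = cfg.psf_sigma_um[0] / dz
    sig_x_px = cfg.psf_sigma_um[1] / dx

    frames = render_clutter(cfg, shape, n_frames, frame_rate)
    frames += render_noise(cfg, shape, n_frames)

    t = np.arange(n_frames) / frame_rate
    mod = 1.0 + cfg.cardiac_mod_depth * np.sin(2 * np.pi * cfg.cardiac_freq_hz * t)
    if len(df):
        sub = df[df["frame"] < n_frames]
        amps: dict[int, tuple[float, complex]] = {}
        for bid, frame, z, x in zip(sub["bubble_id"].to_numpy(int), sub["frame"].to_numpy(int),
                                    sub["z_um"].to_numpy(), sub["x_um"].to_numpy()):
            if bid not in amps:
                amps[bid] = _bubble_draw(cfg.seed, bid, cfg.amp_sigma_log)
            amp, phase = amps[bid]
            _add_gaussian(frames[frame], z / dz, x / dx, amp * phase * mod[frame],
                          sig_z_px, sig_x_px)

    return IQStack(frames, pixel_spacing_um, frame_rate)
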