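import numpy as np
import pytest

from ulmpipe.localize import PSFModel
from ulmpipe.phantom import PhantomConfig, make_vessel_tree, render_iq, simulate_tracks

NATIVE_SPACING_UM = 19.712
MAP_SPACING_UM = 4.928


def add_gaussian(frame, z_px, x_px, amp, sig_z_px, sig_x_px):
    """Reference Gaussian painter (independent re-implementation for tests)."""
    zz, xx = np.meshgrid(np.arange(frame.shape[0], dtype=float),
                         np.arange(frame.shape[1], dtype=float), indexing="ij")
    frame += amp * np.exp(-0.5 * ((zz - z_px) / sig_z_px) ** 2
                          - 0.5 * ((xx - x_px) / sig_x_px) ** 2)
    return frame


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def psf_model():
    return PSFModel(sigma_z_um=40.0, sigma_x_um=60.0)


@pytest.fixture(scope="session")
def straight_geom():
    return make_vessel_tree("straight")


@pytest.fixture(scope="session")
def small_clean_stack(straight_geom):
    """Sparse bubbles, no clutter, light noise; 200 frames at native spacing."""
    tracks = simulate_tracks(straight_geom, 0.2, 1000.0, 0.03, seed=7)
    cfg = PhantomConfig(noise_floor=0.05, noise_depth_slope=0.0, seed=8)
    stack = render_iq(tracks, cfg, n_frames=200)
    return tracks, stack
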