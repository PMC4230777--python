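"""Shared fixtures: small simulated recordings and synthetic movies."""

from __future__ import annotations

import numpy as np
import pytest

import gliaglm as gg


@pytest.fixture(scope="session")
def planted_scenario():
    """Small network with known cross-block connections (fast to search)."""
    return gg.build_scenario(n_neurons=4, n_glia=2, density_gn=0.5,
                             density_ng=0.5, T=20_000, seed=3)


@pytest.fixture(scope="session")
def planted_obs(planted_scenario):
    return gg.simulate(planted_scenario)


@pytest.fixture(scope="session")
def small_obs():
    """Tiny series for plumbing tests (3 neurons, 2 glia, 3000 bins)."""
    scen = gg.build_scenario(n_neurons=3, n_glia=2, density_gn=0.0,
                             density_ng=0.0, T=3_000, seed=11)
    return gg.simulate(scen)


def make_blob_movie(
    centers_px: list[tuple[float, float]],
    shape: tuple[int, int] = (40, 60),
    n_frames: int = 200,
    amplitude: float = 50.0,
    blob_sigma: float = 1.5,
    signal: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Movie with Gaussian blobs at known pixel centres, optional common
    temporal signal and white noise.  Returns (time, rows, cols)."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    base = np.zeros(shape)
    for (r, c) in centers_px:
        base += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                                   / (2 * blob_sigma**2))
    sig = np.ones(n_frames) if signal is None else np.asarray(signal, float)
    movie = 10.0 + sig[:, None, None] * base[None]
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, movie.shape)
    return movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
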