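import numpy as np
import pytest

import specevents as se


@pytest.fixture(scope="session")
def config():
    return se.PipelineConfig()


@pytest.fixture(scope="session")
def beta_band(config):
    return config.band("beta")


@pytest.fixture(scope="session")
def background_1f():
    """Two minutes of 8-channel 1/f background at 500 Hz."""
    return se.gen_background(
        8, 120.0, 500.0, 1.0, 10.0, seed=11,
        channel_labels=se.DEFAULT_ELECTRODES,
    )


def make_normalized_grid(rng, n_f=20, n_t=50, n_bumps=3):
    """Random TFR-like grid: exponential background scaled to row-median 1
    with a few strong localized bumps, wrapped in a normalized TFRStack."""
    grid = rng.exponential(1.0, size=(n_f, n_t))
    grid /= np.median(grid, axis=1, keepdims=True)
    for _ in range(n_bumps):
        f0 = rng.integers(2, n_f - 2)
        t0 = rng.integers(3, n_t - 3)
        amp = rng.uniform(8, 25)
        ff, tt = np.meshgrid(np.arange(n_f), np.arange(n_t), indexing="ij")
        grid += amp * np.exp(
            -((ff - f0) ** 2) / (2 * rng.uniform(0.5, 2.0) ** 2)
            - ((tt - t0) ** 2) / (2 * rng.uniform(1.0, 4.0) ** 2)
        )
    freqs = np.arange(1.0, n_f + 1.0)
    times = np.arange(n_t) * 0.02
    return se.TFRStack(
        power=grid[None, :, :],
        freqs=freqs,
        times=times,
        fs=50.0,
        electrode="Cz",
        normalized=True,
    )


@pytest.fixture
def grid_factory():
    return make_normalized_grid
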