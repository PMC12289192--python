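import numpy as np
import pytest

from fintrack import SceneConfig, generate_trial


def small_config(**overrides) -> SceneConfig:
    """A fast, reduced-scale arena used by most integration tests."""
    params = dict(width=480, height=360, n_obstacles=6, n_frames=60,
                  tank_margin=(40.0, 35.0), obstacle_radius_px=20.0,
                  vp=(215.0, 155.0))
    params.update(overrides)
    return SceneConfig(**params)


@pytest.fixture(scope="session")
def small_trial():
    """One fully rendered small trial shared across tests (read-only)."""
    return generate_trial(small_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def textured_image(rng, shape=(64, 64), background=0.2):
    """Random-texture test image helper."""
    return background + 0.6 * rng.random(shape)
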