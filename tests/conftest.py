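import numpy as np
import pytest

from maizephen import ChannelConfig, SceneConfig, generate_scene, scene_feature_table


@pytest.fixture(scope="session")
def small_config():
    """A compact six-stage scene: 36 plots of 10x10 px (6 per stage)."""
    return SceneConfig(
        grid_height=80, grid_width=160, n_plots=36,
        plot_height=10, plot_width=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def small_table(small_scene):
    return scene_feature_table(small_scene, ChannelConfig())


@pytest.fixture(scope="session")
def zero_noise_scene():
    cfg = SceneConfig(
        grid_height=60, grid_width=120, n_plots=18,
        plot_height=8, plot_width=8, noise_sd=0.0, seed=5,
    )
    return generate_scene(cfg)


def random_mask(rng: np.random.Generator, shape, density: float = 0.65,
                require_connected_neighbours: bool = False) -> np.ndarray:
    """Random boolean mask with at least 2 pixels; optionally no isolated
    pixels (every masked pixel has a masked queen neighbour)."""
    while True:
        mask = rng.random(shape) < density
        if mask.sum() < 2:
            continue
        if require_connected_neighbours and _has_isolated(mask):
            continue
        return mask


def _has_isolated(mask: np.ndarray) -> bool:
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=int)
    padded[1:-1, 1:-1] = mask
    neigh = sum(
        padded[1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    )
    return bool(np.any(mask & (neigh == 0)))
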