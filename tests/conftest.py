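import numpy as np
import pytest

from untca.backbone import reduced_config
from untca.synth import SceneConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_scene_config(size: int = 64) -> SceneConfig:
    """Scene parameters scaled to a 64-px canvas (few, small cells)."""
    return SceneConfig(image_size=size, n_cells=5, axis_range=(4.0, 9.0),
                       elongation_range=(0.4, 0.75))


@pytest.fixture(scope="session")
def small_dataset():
    """16 tiny images (10 clear / 4 occluded / 2 blurred) shared by tests."""
    samples, manifest = generate_dataset(
        16, (10, 4, 2), size=64, seed=123, base_config=small_scene_config())
    return samples, manifest


@pytest.fixture()
def tiny_model_cfg():
    """Smallest config that still exercises every mechanism (depth 3)."""
    return reduced_config(dropout=0.0)
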