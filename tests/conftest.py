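import numpy as np
import pytest

from endoclear import SceneConfig, generate_scene, remove_highlights


@pytest.fixture
def scene7():
    """Default synthetic scene, seed 7."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def batch20():
    """Twenty seeded default scenes run through the full pipeline.

    Shared across test modules: each entry is (scene, RemovalOutput).
    """
    runs = []
    for seed in range(20):
        scene = generate_scene(SceneConfig(seed=seed))
        runs.append((scene, remove_highlights(scene.composite)))
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
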