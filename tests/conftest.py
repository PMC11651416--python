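import numpy as np
import pytest

from pointline.geometry import Box
from pointline.synthdata import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def early_scene():
    """One deterministic early-stage synthetic scene (image, annotations)."""
    return generate_scene(SceneConfig.for_stage("early", seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0.0, hi=100.0, min_side=1.0):
    x1, y1 = rng.uniform(lo, hi - min_side, size=2)
    w, h = rng.uniform(min_side, (hi - lo) / 2, size=2)
    return Box(x1, y1, min(x1 + w, hi), min(y1 + h, hi))
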