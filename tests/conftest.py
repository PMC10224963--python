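import numpy as np
import pytest

from wildcount.scene import Scene, PointSet
from wildcount.synthetic import SceneSpec, generate_scene


@pytest.fixture
def small_scene() -> Scene:
    """A deterministic 4-band 64x64 scene at 0.5 m."""
    rng = np.random.default_rng(42)
    bands = rng.integers(200, 1200, size=(4, 64, 64)).astype(np.uint16)
    return Scene(bands, 0.5, origin=(100.0, 500.0), crs_label="test-meters")


@pytest.fixture
def synthetic_pair():
    """A 96x96 synthetic scene with 8 well-separated animals + ground truth."""
    spec = SceneSpec(width_px=96, height_px=96, n_animals=8,
                     min_separation_px=5.0, seed=7)
    return generate_scene(spec)


def random_pointset(rng: np.random.Generator, n: int, extent=100.0) -> PointSet:
    return PointSet(rng.uniform(0, extent, size=(n, 2)))
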