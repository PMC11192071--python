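import numpy as np
import pytest

from mulchmap import synthetic_scene as sc
from mulchmap.geo_io import extract_training_pixels


@pytest.fixture(scope="session")
def library():
    return sc.default_spectral_library()


@pytest.fixture(scope="session")
def small_scene(library):
    """A compact scene shared by tests that only need plausible data."""
    cfg = sc.SceneConfig(height=64, width=64, seed=11)
    vnir, swir, truth = sc.generate_scene(cfg, library)
    return cfg, vnir, swir, truth


@pytest.fixture(scope="session")
def small_polygons(small_scene):
    _, _, _, truth = small_scene
    plan = sc.scaled_training_plan(area_scale=0.03)
    return sc.generate_training_polygons(truth, plan, seed=12)


@pytest.fixture(scope="session")
def swir_training(small_scene, small_polygons):
    _, _, swir, _ = small_scene
    return extract_training_pixels(swir, small_polygons,
                                   class_names=list(sc.CLASS_NAMES))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
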