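import warnings

import numpy as np
import pytest

from mabveg import segmentation as seg
from mabveg import stratification as st
from mabveg.mab_model import default_mab_table
from mabveg.scene_synthesis import SceneParams, generate_scene


@pytest.fixture(scope="session")
def table():
    return default_mab_table()


@pytest.fixture(scope="session")
def small_scene():
    """Shared noisy 96x96 scene used by several module tests."""
    return generate_scene(SceneParams(rows=96, cols=96, seed=7))


@pytest.fixture(scope="session")
def small_segmented(small_scene):
    """(object map, feature table) of the shared scene at a fine scale."""
    stack = seg.build_stack(small_scene.image, small_scene.dsm)
    om = seg.segment(stack, seg.SegmentationParams(scale=5.0))
    feats = seg.compute_features(om, small_scene.image, small_scene.dsm)
    return om, feats


@pytest.fixture(scope="session")
def small_stratified(small_scene, table):
    mask = st.split_slopes(small_scene.dsm)
    belts = st.build_constraint_raster(small_scene.dsm, mask, table)
    return mask, belts


@pytest.fixture(autouse=True)
def _quiet_sampling_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="candidate filter removed")
        warnings.filterwarnings("ignore", message="fewer than 2 samples")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
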