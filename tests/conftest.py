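import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phenotag as pt

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    return pt.build_default_scheme()


@pytest.fixture(scope="session")
def small_feat_cfg():
    """Low-dimensional feature clusters for fast classifier tests."""
    return pt.FeatureSimConfig(dim=16, centroid_scale=6.0, spread=1.0, seed=42)


@pytest.fixture(scope="session")
def small_field(scheme):
    cfg = pt.PhenologyFieldConfig(
        width_km=100, height_km=100, cell_km=10, seed=3,
    )
    return pt.PhenologyField(cfg, scheme)


@pytest.fixture(scope="session")
def tiny_feature_set(scheme, small_feat_cfg):
    """12 records per class, 39 classes, 16-d features."""
    sizes = {cls: 12 for cls in scheme.classes}
    cfg = pt.FeatureSimConfig(dim=16, centroid_scale=6.0, spread=1.0,
                              class_sizes=sizes, seed=42)
    return pt.generate_feature_dataset(cfg, scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
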