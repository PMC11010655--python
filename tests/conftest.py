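import numpy as np
import pytest

from eipdt import (
    ModernDataset,
    RadiusSpec,
    SyntheticConfig,
    generate_fossil_core,
    generate_modern,
    to_percentages,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def modern_world(default_cfg):
    """Default synthetic modern calibration set (percentages) with truth."""
    ds, truth = generate_modern(default_cfg)
    return ModernDataset(to_percentages(ds.pollen), ds.meta), truth


@pytest.fixture(scope="session")
def radius_spec(default_cfg):
    return RadiusSpec(default_cfg.center_lon, default_cfg.center_lat)


@pytest.fixture(scope="session")
def fossil_world(default_cfg):
    """Default six-phase synthetic fossil core with truth."""
    return generate_fossil_core(default_cfg)


@pytest.fixture(scope="session")
def small_world():
    """A small, quick synthetic world for unit tests."""
    cfg = SyntheticConfig(seed=5, n_modern=150)
    ds, truth = generate_modern(cfg)
    return ModernDataset(to_percentages(ds.pollen), ds.meta), truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
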