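import numpy as np
import pytest

from kneespect import (
    HotSpot,
    PhantomConfig,
    build_report,
    make_phantom,
    partition_volume,
)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Native right-knee phantom with uniform uptake (baseline == reference)."""
    return make_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def uniform_labelmap(uniform_phantom):
    vol, lms, _ = uniform_phantom
    return partition_volume(vol, lms, "native")


@pytest.fixture(scope="session")
def hot_phantom():
    """Medial tibial hot spot: amplitude 8 over baseline 2, reference 2 (ratio 5)."""
    cfg = PhantomConfig(
        baseline=2.0,
        reference_level=2.0,
        hotspots=(HotSpot(zone="T1sa", amplitude=8.0, radius_mm=6.0),),
    )
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def hot_report(hot_phantom):
    vol, lms, _ = hot_phantom
    return build_report(vol, lms, "native")


@pytest.fixture(scope="session")
def postop_phantom():
    cfg = PhantomConfig(
        variant="postoperative",
        hotspots=(HotSpot(zone="T4", amplitude=100.0, radius_mm=6.0),),
    )
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
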