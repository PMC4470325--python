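import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_geometry():
    from mrsim.meniscus import ContactGeometry

    return ContactGeometry()  # 5 um bead, theta_p 60 deg, theta_s 30 deg


@pytest.fixture(scope="session")
def family70(default_geometry):
    """Full default shape family (70 shapes)."""
    from mrsim.meniscus import build_family

    return build_family(default_geometry, n_shapes=70)


@pytest.fixture(scope="session")
def family20(default_geometry):
    """Desk-scale shape family (20 shapes) for ray-tracing runs."""
    from mrsim.meniscus import build_family

    return build_family(default_geometry, n_shapes=20)


@pytest.fixture(scope="session")
def small_family(default_geometry):
    """Tiny family for cheap unit tests."""
    from mrsim.meniscus import build_family

    return build_family(default_geometry, n_shapes=6, scan_points=24)


@pytest.fixture(scope="session")
def enhancement_results(family20):
    """Fast-budget enhancement scan over the 20-shape family at NA 0.13.

    Shared by the collection-enhancement and NA-dependence tests; the bare
    sphere and every shape are traced with common random numbers.
    """
    from mrsim.enhancement import enhancement_vs_shape
    from mrsim.raytrace import TraceConfig

    config = TraceConfig.fast(rng_seed=0)
    curve, detectors, det_bare = enhancement_vs_shape(
        family20, config, na=0.13, return_detectors=True
    )
    return {"curve": curve, "detectors": detectors, "det_bare": det_bare, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
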