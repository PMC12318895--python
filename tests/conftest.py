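import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basic_tissue():
    """One seeded zonated tissue with planted artefacts and debris."""
    from gcspatial.scenarios import basic_tissue_spec
    from gcspatial.synthetic import simulate_tissue

    return simulate_tissue(basic_tissue_spec(seed=1, artefact_fraction=0.1,
                                             debris_fraction=0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def unit_disc_roi():
    from shapely.geometry import Point

    from gcspatial.follicles import FollicleROI

    disc = Point(0.0, 0.0).buffer(300.0, quad_segs=128)
    return FollicleROI("F0", disc, disc.area, (0.0, 0.0), 0)
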