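import numpy as np
import pytest
from shapely.geometry import Point

from sdindex.pipeline import run_on_bundle
from sdindex.synthetic import CityConfig, generate_city, generate_edge_cases


@pytest.fixture(scope="session")
def city_bundle():
    return generate_city(CityConfig(seed=1))


@pytest.fixture(scope="session")
def city_run(city_bundle):
    return run_on_bundle(city_bundle)


@pytest.fixture(scope="session")
def geo_bundle():
    return generate_city(CityConfig(seed=1, crs="geographic"))


@pytest.fixture(scope="session")
def geo_run(geo_bundle):
    return run_on_bundle(geo_bundle)


@pytest.fixture(scope="session")
def edge_bundle():
    return generate_edge_cases(seed=3)


@pytest.fixture(scope="session")
def edge_run(edge_bundle):
    return run_on_bundle(edge_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


def record_at(records, x, y):
    """The unique score record whose unit contains the point (x, y)."""
    hits = [r for r in records if r.geometry.contains(Point(x, y))]
    assert len(hits) == 1, f"expected exactly one unit at ({x}, {y}), got {len(hits)}"
    return hits[0]
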