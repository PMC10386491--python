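import numpy as np
import pytest

from poreflux import (
    GeometryNoiseConfig,
    SiteModel,
    build_pore_template,
    derive_boundaries,
)


@pytest.fixture(scope="session")
def site_model():
    return SiteModel()


@pytest.fixture(scope="session")
def noise():
    return GeometryNoiseConfig()


@pytest.fixture(scope="session")
def boundaries(site_model):
    return derive_boundaries(site_model.z_p23, site_model.z_p34)


@pytest.fixture(scope="session")
def template(site_model, noise):
    """Default tetramer template: (AtomTable, coords)."""
    return build_pore_template(site_model, noise)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
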