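import numpy as np
import pytest

from capsidarch.g2t import fit_g2t
from capsidarch.lattice import enumerate_architectures
from capsidarch.rf import build_class_scheme, featurize_library
from capsidarch.simulate import (
    default_class_profiles,
    load_highres_fixture,
    simulate_mcp_classes,
)

REFERENCE_MRE = 0.09


@pytest.fixture(scope="session")
def highres_records():
    return load_highres_fixture()


@pytest.fixture(scope="session")
def g2t_fit(highres_records):
    return fit_g2t(highres_records)


@pytest.fixture(scope="session")
def architectures():
    return enumerate_architectures(60)


@pytest.fixture(scope="session")
def scheme(architectures, g2t_fit):
    return build_class_scheme(architectures, g2t_fit, REFERENCE_MRE)


@pytest.fixture(scope="session")
def sep_library(g2t_fit):
    """Three well-separated composition classes, genome lengths consistent
    with the fitted allometric model (60 entries per class)."""
    return simulate_mcp_classes(
        default_class_profiles(), n_per_class=60, seed=11, fit=g2t_fit
    )


@pytest.fixture(scope="session")
def sep_features(sep_library):
    return featurize_library(sep_library)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
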