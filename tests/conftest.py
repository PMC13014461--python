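import warnings

import numpy as np
import pytest
from hypothesis import settings

from torsionsmith.synthetic import make_fixture

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixtures():
    """Session cache of the built-in toy molecules (treated as read-only)."""
    return {name: make_fixture(name)
            for name in ("butane_like", "biphenyl_like", "amide_chain",
                         "two_region", "rigid_ring")}


@pytest.fixture
def butane(fixtures):
    return fixtures["butane_like"]


@pytest.fixture(autouse=True)
def _quiet_minimizer_warnings():
    """Non-converged-minimization warnings are expected on a few deliberately
    strained test geometries; keep assertions, drop the noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
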