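import numpy as np
import pytest

from avci.likelihoods import QuadratureSpec
from avci.params import PAPER_REGIME, ObserverParams
from avci.recovery import FAST_SPEC
from avci.simulate import DEFAULT_DESIGN, simulate_all


@pytest.fixture(scope="session")
def regime() -> ObserverParams:
    """Generating observer in the underestimation regime (employed ≈ actual/2)."""
    return PAPER_REGIME


@pytest.fixture(scope="session")
def fast_spec() -> QuadratureSpec:
    return FAST_SPEC


@pytest.fixture(scope="session")
def reduced_session(regime):
    """One quarter-scale synthetic session."""
    return simulate_all(DEFAULT_DESIGN.reduced(), regime, seed=20241)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
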