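import numpy as np
import pytest

from riskfix import PayoffScheme, parse_scheme


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def baseline():
    """Symmetric 5-10-15 scheme: risk-prone draws 5 or 15 equiprobably."""
    return parse_scheme("5-10-15")


@pytest.fixture(scope="session")
def zero_variance():
    """Degenerate scheme where both strategies earn 10 every event."""
    return PayoffScheme(low=10.0, high=10.0, risk_averse=10.0, p_high=0.5)
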