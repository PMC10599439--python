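import pytest

from dslattice import BindingParameters


@pytest.fixture(scope="session")
def property_grid():
    """(omega1, omega2, x) grid spanning negative through strong positive
    cooperativity, used by several cross-method equivalence tests."""
    omegas = [0.5, 1.0, 2.0, 17.0]
    xs = [0.1, 1.0, 10.0]
    return [
        (BindingParameters(omega1=w1, omega2=w2), x)
        for w1 in omegas
        for w2 in omegas
        for x in xs
    ]


@pytest.fixture(scope="session")
def wt_params():
    """Cooperativities of the wild-type cofilin fit (lateral ~1, strong
    longitudinal)."""
    return BindingParameters(omega1=0.89, omega2=36.2)
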