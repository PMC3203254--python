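import pytest

from rtasim import SolverSettings, table2_defaults


@pytest.fixture(scope="session")
def params():
    """Canonical nondimensional parameter set (k3 = 3.3e-5)."""
    return table2_defaults()


@pytest.fixture(scope="session")
def params_k3_0(params):
    """Same set without internalization, as used by the steady-state theory."""
    return params.replace(k3=0.0)


@pytest.fixture(scope="session")
def fast_settings():
    """Coarse PDE discretization for quick qualitative checks."""
    return SolverSettings(N=101, dt=1.0)
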