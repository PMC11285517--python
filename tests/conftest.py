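import numpy as np
import pytest

import finetoggle as ft


@pytest.fixture(scope="session")
def dimer_model():
    """Default parameterization, dimer regulation."""
    return ft.build_model(2)


@pytest.fixture(scope="session")
def tripartite_model():
    """gamma3 x10: the canonical three-attractor regime."""
    return ft.build_model(2, ft.RateSet().scaled_by({"gamma3": 10}))


@pytest.fixture(scope="session")
def scan_settings():
    """Adaptive solver with the windowed convergence criterion."""
    return ft.SolverSettings(method="lsoda")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240246)
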