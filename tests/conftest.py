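import numpy as np
import pytest

from chiralflow import AxialProfile, ModelParams, SolverConfig


@pytest.fixture
def bins18():
    """18 AP bin centres on a 50 um embryo."""
    edges = np.linspace(0.0, 50.0, 19)
    return 0.5 * (edges[:-1] + edges[1:])


@pytest.fixture
def sigmoid_intensity(bins18):
    """Anterior-high myosin-like gradient, dropping in the posterior half."""
    return AxialProfile(bins18, 0.5 + 1.0 / (1.0 + np.exp(0.2 * (bins18 - 30.0))))


@pytest.fixture
def reference_params():
    """Parameters in the measured non-RNAi regime."""
    return ModelParams(ell=16.0, alpha=10.0, beta=5.8)


@pytest.fixture
def solver_cfg():
    return SolverConfig()
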