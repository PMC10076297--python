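import numpy as np
import pytest

from itnet.graphs import build_base_topology, random_connected_digraph
from itnet.model import NetworkModel
from itnet.optimize import DesignSpec

#: reference conditions of the 6-node experiments: Σ0 = 5I, B = 0.1I, t = 10
EXAMPLE_PARAMS = {"Sigma0": 5.0, "B1": 0.1, "t": 10.0}


@pytest.fixture
def nilpotent_model():
    """2-node feed-forward model with closed-form covariance:
    Σ(1) = [[1.260833, 0.5025], [0.5025, 1.01]] (A nilpotent, e^{At} = I+At)."""
    return NetworkModel(
        A=[[0.0, 0.5], [0.0, 0.0]],
        B1=0.1 * np.eye(2),
        mu0=[0.0, 1.0],
        Sigma0=np.eye(2),
    )


@pytest.fixture
def base6_spec():
    """Design spec on the 6-node base topology for T_{3→1} under the
    reference experiment conditions."""
    g = build_base_topology(6, j=3, i=1)
    return DesignSpec(graph=g, j=3, i=1, k=0, Sigma0=5.0, B1=0.1, t=10.0)


@pytest.fixture
def update_spec():
    """A random-connected 6-node/10-edge update instance for T_{5→2}
    under the reference update-problem weight bounds."""
    g = random_connected_digraph(6, 10, seed=3)
    return DesignSpec(
        graph=g, j=5, i=2, k=5, w_max=4.2, w_ub=1.0, Sigma0=5.0, B1=0.1, t=10.0
    )


def random_stable_model(n, rng, nilpotent=False):
    """Random n-node model, either strictly upper-triangular (nilpotent)
    or diagonally shifted to be Hurwitz-stable."""
    A = rng.normal(size=(n, n))
    np.fill_diagonal(A, 0.0)
    if nilpotent:
        A = np.triu(A, k=1)
    else:
        A = A - (np.abs(A).sum(axis=1).max() + 0.5) * np.eye(n)
    B = rng.normal(size=(n, n)) * 0.3
    S0 = rng.normal(size=(n, n))
    S0 = S0 @ S0.T + 0.1 * np.eye(n)
    return NetworkModel(A=A, B1=B, mu0=np.zeros(n), Sigma0=S0)
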