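import numpy as np
import pytest

from sensnet.model import MetabolicModel, Metabolite, Reaction
from sensnet.sensitivity import sensitivity_matrix
from sensnet.synthetic import make_network


def _mets(*names):
    return [Metabolite(id=f"{n}_c", name=n, compartment="c") for n in names]


def canon(name: str) -> str:
    return f"{name}[c]"


@pytest.fixture
def branch_model():
    """A -> 2 branches: r1 produces A, r2 and r3 consume it (N = [1, -1, -1])."""
    return MetabolicModel(
        id="branch",
        metabolites=_mets("A"),
        reactions=[
            Reaction(id="r1", stoichiometry={canon("A"): 1.0}),
            Reaction(id="r2", stoichiometry={canon("A"): -1.0}),
            Reaction(id="r3", stoichiometry={canon("A"): -1.0}),
        ],
    )


@pytest.fixture
def chain_model():
    """Single metabolite chain: r1 produces A, r2 consumes it (N = [1, -1])."""
    return MetabolicModel(
        id="chain",
        metabolites=_mets("A"),
        reactions=[
            Reaction(id="r1", stoichiometry={canon("A"): 1.0}),
            Reaction(id="r2", stoichiometry={canon("A"): -1.0}),
        ],
    )


@pytest.fixture(scope="session")
def medium_network():
    return make_network(seed=11, n_metabolites=25, n_reactions=40)


@pytest.fixture(scope="session")
def medium_sensitivities(medium_network):
    return sensitivity_matrix(medium_network)


def random_stoichiometric_matrix(rng, max_mets=20, max_rxns=30):
    """Random sparse integer stoichiometry with guaranteed extra columns."""
    m = int(rng.integers(2, max_mets + 1))
    n = int(rng.integers(m + 1, max_rxns + 1))
    N = np.zeros((m, n))
    for j in range(n):
        k = int(rng.integers(1, min(4, m + 1)))
        rows = rng.choice(m, size=k, replace=False)
        N[rows, j] = rng.choice([-2, -1, 1, 2], size=k)
    return N


def least_norm_oracle(N, k, delta=1.0):
    """Independent least-norm solve of the perturbation problem.

    Minimize ||d|| subject to N d = 0 and d_k = delta, via the stacked
    linear system solved by lstsq (which returns the minimum-norm solution
    of a consistent underdetermined system).
    """
    m, n = N.shape
    A = np.vstack([N, np.eye(n)[k]])
    b = np.concatenate([np.zeros(m), [delta]])
    d, *_ = np.linalg.lstsq(A, b, rcond=None)
    return d
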