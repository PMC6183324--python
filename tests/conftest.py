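import numpy as np
import pytest

from shiftanp.network import load_network, load_shiftwork_network
from shiftanp.pairwise import SAATY_GRID


@pytest.fixture(scope="session")
def shiftwork_net():
    """Bundled network with the default inner dependence among criteria."""
    return load_shiftwork_network()


@pytest.fixture(scope="session")
def hierarchy_net():
    """Bundled network reduced to the pure hierarchy (no feedback)."""
    return load_shiftwork_network(criteria_feedback=False)


MINIMAL_CONFIG = {
    "name": "toy",
    "goal": {"id": "goal", "label": "pick one"},
    "structure": {"hierarchy": True},
    "clusters": [
        {"id": "criteria", "kind": "criteria",
         "members": [{"id": "c1", "label": "only criterion"}]},
        {"id": "alternatives", "kind": "alternatives",
         "members": [{"id": "a1"}, {"id": "a2"}]},
    ],
}


@pytest.fixture()
def minimal_net():
    """Smallest legal hierarchy: one criterion, two alternatives."""
    return load_network(MINIMAL_CONFIG)


def random_reciprocal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random judgment matrix with entries on the 17-value grid."""
    a = np.eye(n)
    iu, ju = np.triu_indices(n, 1)
    vals = rng.choice(SAATY_GRID, size=len(iu))
    a[iu, ju] = vals
    a[ju, iu] = 1.0 / vals
    return a
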