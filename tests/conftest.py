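import numpy as np
import pytest

from promnet import SimConfig, generate_cohort
from promnet.synthetic import _ggm_from_partials


def make_truth_from_edges(p, edges, seed=0):
    """Ground truth with the given (i, j, partial) edges."""
    w = np.zeros((p, p))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return _ggm_from_partials(w, seed)


@pytest.fixture(scope="session")
def chain3_truth():
    """3-node chain with both partials 0.4."""
    return make_truth_from_edges(3, [(0, 1, 0.4), (1, 2, 0.4)])


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(n_patients=120, seed=11))


def random_weights(p, rng, density=0.5, scale=0.3):
    """Random symmetric zero-diagonal weight matrix (not necessarily a
    valid partial-correlation matrix; fine for metric identities)."""
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    vals = rng.uniform(-scale, scale, size=iu[0].size)
    vals[rng.random(iu[0].size) > density] = 0.0
    w[iu] = vals
    return w + w.T
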