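import numpy as np
import pytest

import chromsaliency as cs


@pytest.fixture
def small_matrix():
    """3 biosamples x 6 bins x 3 states, fixed seed — a generic tiny input."""
    rng = np.random.default_rng(42)
    states = rng.integers(0, 3, size=(3, 6))
    from helpers import matrix_from_rows

    return matrix_from_rows(states, n_states=3)


@pytest.fixture
def default_sim():
    """A mid-sized simulated dataset under the default study conditions."""
    spec = cs.SimulationSpec(n_bins=5_000, m_biosamples=10, seed=123)
    return cs.simulate_matrix(spec)
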