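import numpy as np
import pytest

from psychembed.kernel import KernelParams
from psychembed.likelihood import PsychEmbedding
from psychembed.trials import Observations


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def small_embedding(rng):
    """A 10-stimulus, 2-D embedding with an exponential kernel."""
    z = rng.normal(0.0, 0.2, size=(10, 2))
    return PsychEmbedding(z, KernelParams(family="exponential", beta=5.0))


def random_observations(rng, n_stimulus=12, n_trial=30, n_group=1,
                        max_select=3):
    """Random valid observations with heterogeneous configurations.

    ``max_select`` caps the selection count (large unranked selections are
    legal but combinatorially explosive and unrealistic as displays).
    """
    rows = np.full((n_trial, 9), -1, dtype=np.int64)
    n_select = np.empty(n_trial, dtype=np.int64)
    is_ranked = np.empty(n_trial, dtype=bool)
    for i in range(n_trial):
        m = int(rng.integers(2, min(9, n_stimulus)))
        rows[i, : 1 + m] = rng.choice(n_stimulus, size=1 + m, replace=False)
        n_select[i] = int(rng.integers(1, min(m, max_select + 1)))
        is_ranked[i] = bool(rng.random() < 0.5)
    group = rng.integers(0, n_group, size=n_trial)
    return Observations(rows, n_select, is_ranked, group)


@pytest.fixture
def mixed_observations(rng):
    return random_observations(rng)
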