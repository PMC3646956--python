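import numpy as np
import pytest

from skystruct import Genealogy, SamplingScheme, StructuredModel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def panmictic_model():
    """Single deme of 20,000 females (the census of the 40x500 scenarios)."""
    return StructuredModel(deme_sizes=np.array([20000.0]), migration=np.zeros((1, 1)))


def make_genealogy(coal_times, tip_demes=None):
    """Caterpillar genealogy with given sorted coalescence times (generations)."""
    times = list(coal_times)
    n = len(times) + 1
    if tip_demes is None:
        tip_demes = [0] * n
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_times = np.zeros(2 * n - 1)
    # tips 0,1 join first; each later tip joins the growing spine
    parent[0] = parent[1] = n
    node_times[n] = times[0]
    for i, t in enumerate(times[1:], start=1):
        node = n + i
        parent[n + i - 1] = node
        parent[i + 1] = node
        node_times[node] = t
    return Genealogy(n_tips=n, tip_demes=np.asarray(tip_demes), parent=parent,
                     node_times=node_times)


@pytest.fixture
def pair_scheme():
    return SamplingScheme("scattered", {0: 1, 1: 1}, 2)
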