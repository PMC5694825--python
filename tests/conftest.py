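import numpy as np
import pytest

from connectocast import metrics as cm
from connectocast import synth


def net_from_adj(adj) -> cm.BinaryNetwork:
    adj = np.asarray(adj, dtype=int)
    n = adj.shape[0]
    n_pairs = n * (n - 1) // 2
    return cm.BinaryNetwork(
        labels=[f"R{i:03d}" for i in range(n)],
        adjacency=adj,
        density=int(adj.sum() // 2) / n_pairs,
    )


def random_binary_net(rng: np.random.Generator, n: int, p: float) -> cm.BinaryNetwork:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(int)
    return net_from_adj(adj)


@pytest.fixture(scope="session")
def small_cohort() -> synth.SyntheticCohort:
    """A compact planted-signal cohort shared by read-only tests."""
    cfg = synth.CohortConfig(
        n_patients=24,
        n_controls=20,
        n_regions=24,
        n_modules=3,
        predictive_regions=(2, 10, 18),
        matrix_timepoints=("baseline",),
        seed=7,
    )
    return synth.generate_cohort(cfg)
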