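import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from exprevo.tree import OUParams, drosophila_tree

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree():
    return drosophila_tree()


@pytest.fixture(scope="session")
def sos(tree):
    """species_of_sample for three replicates per species."""
    return [sp for sp in tree.tip_names for _ in range(3)]


def replicate_matrix(means: np.ndarray, rng, sigma2_e: float, n_reps: int = 3):
    """Expand genes x species means to genes x (species*reps) with noise."""
    reps = np.repeat(means, n_reps, axis=1)
    return reps + rng.normal(0, sigma2_e**0.5, reps.shape)


@pytest.fixture(scope="session")
def ou_params():
    return OUParams(0.5, 0.25, 0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
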