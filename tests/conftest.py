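import numpy as np
import pytest

from mvewas.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across test modules."""
    cfg = CohortConfig(
        n_samples=120, n_clusters=4, probes_per_cluster=25, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
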