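import numpy as np
import pytest

from modnet import (
    EstimatorSettings,
    build_truth,
    default_panel,
    rotate_references,
    sample_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def null_truth():
    """Two groups sharing one distribution: no planted differences."""
    return build_truth(G=2, n_planted_mean=0, n_planted_edge=0, seed=7)


@pytest.fixture(scope="session")
def small_truth():
    """Three groups with a couple of planted mean shifts and one edge shift."""
    return build_truth(
        G=3, n_planted_mean=2, n_planted_edge=1, effect_mean=0.5, seed=3
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return sample_cohort(small_truth, [180, 150, 120], ordinal=True, seed=4)


@pytest.fixture(scope="session")
def null_cohort(null_truth):
    return sample_cohort(null_truth, [250, 200], ordinal=True, seed=9)


@pytest.fixture(scope="session")
def zero_penalty_settings():
    """A path ending at an exact zero penalty (unpenalized final fit)."""
    return EstimatorSettings(lambda_path=(1e-6, 0.0))


@pytest.fixture(scope="session")
def small_ensemble_zero_penalty(small_cohort, zero_penalty_settings):
    return rotate_references(small_cohort, zero_penalty_settings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
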