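import numpy as np
import pytest

from pedalbp import PipelineConfig, SyntheticConfig, generate_cohort
from pedalbp.pipeline import cohort_lag_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """Eight synthetic subjects, 120 s each, default nuisance levels."""
    cfg = SyntheticConfig(n_subjects=8, duration_range=(120.0, 120.0), seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_lag_matrix(small_cohort):
    return cohort_lag_matrix(small_cohort, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
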