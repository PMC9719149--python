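import numpy as np
import pytest

from abratio import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default (reference-cohort) parameters."""
    return generate_cohort(CohortConfig(seed=20240901))


@pytest.fixture(scope="session")
def clean_cohort():
    """78-subject low-technical-noise cohort: QC violations only where injected."""
    return generate_cohort(CohortConfig(n_neg=40, n_pos=38, replicate_cv_pct=3.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
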