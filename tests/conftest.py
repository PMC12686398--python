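import numpy as np
import pytest

from mammoage.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small deterministic cohort shared by IO-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(n_patients=6, exams_per_patient=(1, 2),
                       image_shape=(64, 32), noise_sd=0.01,
                       cancer_fraction=0.5, seed=7)
    records, manifest = generate_cohort(cfg, out)
    return cfg, records, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
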