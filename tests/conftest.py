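import numpy as np
import pytest

from compscore.synthetic_data import CohortConfig, simulate_variant_cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """A moderately sized cohort with a clearly informative assay and predictor."""
    cfg = CohortConfig(
        n_disease=300,
        n_nondisease=300,
        assay_sensitivity=0.85,
        assay_specificity=0.9,
        predictor_auroc=0.85,
        seed=7,
    )
    return simulate_variant_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
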