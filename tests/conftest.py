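import numpy as np
import pytest

from lnrads import GeneratorConfig, features_from_records, sample_cohort


@pytest.fixture(scope="session")
def big_cohort():
    """Large default-configuration cohort for law-of-large-numbers checks."""
    return sample_cohort(GeneratorConfig(n=100_000, seed=12345))


@pytest.fixture(scope="session")
def fast_cohort():
    """Desk-scale cohort with feature vectors, malignancy labels and levels."""
    records = sample_cohort(GeneratorConfig(n=2000, seed=7))
    X = features_from_records(records, seed=7)
    y = np.array([r.malignant for r in records])
    levels = [r.lnrads for r in records]
    return records, X, y, levels
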