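import numpy as np
import pytest

from motifkit.synthetic import default_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects per (genotype, sex) cell, 10-min sessions, 30 motifs."""
    spec = default_spec(n_subjects=2, session_minutes=10.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
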