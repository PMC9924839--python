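import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecglvh as e

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 11 s, 72 bpm, 500 Hz 12-lead record with exact truth."""
    return e.synth_record(seed=11, noise_sd=0.0, rr_jitter=0.0)


@pytest.fixture(scope="session")
def clean_annotations(clean_record):
    seq, _ = clean_record
    return e.detect_record(seq)


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject synthetic cohort: records, truth, and feature table."""
    spec = e.CohortSpec(n_lvh=10, n_control=10, seed=3)
    return e.synth_cohort(spec)
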