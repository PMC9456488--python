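import numpy as np
import pytest

from ecgrobust.synth import (SyntheticPatient, default_template,
                             generate_cohort, generate_record)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(4, seed=11)


@pytest.fixture(scope="session")
def steady_patient():
    """60 bpm, no RR jitter, no lead jitter: fully predictable timing."""
    return SyntheticPatient(
        patient_id="steady",
        class_label="NOR",
        heart_rate_bpm=60.0,
        template=default_template(),
        rr_jitter=0.0,
        lead_amp_jitter=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def synthetic_record(small_cohort):
    record, peaks = generate_record(small_cohort[0], n_leads=3, duration_s=12.0)
    return record, peaks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
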