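import numpy as np
import pytest

from embidetect import healthy_spec, patient_spec, run_cohort_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_run():
    """Full healthy-regime benchmark: 40 recordings, train on 20, test on 20."""
    result, detector, dataset = run_cohort_benchmark(
        healthy_spec(), n_recordings=40, seed=42
    )
    return result, detector, dataset


@pytest.fixture(scope="session")
def patient_run():
    """Full patient-regime benchmark (degraded SNR, wider timing)."""
    result, detector, dataset = run_cohort_benchmark(
        patient_spec(), n_recordings=40, seed=43
    )
    return result, detector, dataset
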