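import numpy as np
import pytest

from clasphase import AnalysisParams, SimConfig, run_cohort


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def small_sim():
    return SimConfig(n_subjects=3, duration_s=1800.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_sim, params):
    """Three subjects × 30 min, fully processed, EEG retained for ERPs."""
    return run_cohort(small_sim, params, keep_eeg=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
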