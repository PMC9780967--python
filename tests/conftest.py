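import numpy as np
import pytest

from wotrack.synth import NoiseProfile, default_params, simulate_session
from wotrack.triggers import binarize_session

#: Published condition statistics used as recovery targets in tests:
#: feature -> (mean, sd) per condition.
TABLE1 = {
    "pre": {
        "stride_time_ms": (1081.09, 72.01),
        "cocon_lg_ta_ms": (113.74, 32.12),
        "cocon_rf_bf_ms": (232.51, 50.04),
        "dc_lg_pct": (24.78, 3.70),
        "dc_ta_pct": (63.48, 5.44),
        "dc_rf_pct": (56.29, 5.49),
        "dc_bf_pct": (23.31, 2.42),
    },
    "post": {
        "stride_time_ms": (1044.64, 34.49),
        "cocon_lg_ta_ms": (106.16, 29.19),
        "cocon_rf_bf_ms": (228.02, 17.00),
        "dc_lg_pct": (24.34, 3.70),
        "dc_ta_pct": (63.49, 5.44),
        "dc_rf_pct": (57.49, 5.49),
        "dc_bf_pct": (23.54, 2.42),
    },
}


@pytest.fixture(scope="session")
def pre_session():
    """A medium pre-Levodopa run at default SNR, with EEG."""
    return simulate_session(default_params("pre"), 60, seed=42,
                            noise=NoiseProfile(), include_eeg=True)


@pytest.fixture(scope="session")
def pre_triggers(pre_session):
    return binarize_session(pre_session)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
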