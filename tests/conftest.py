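import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import physioscreen as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def clean_effect():
    """Deterministic, noise-free effect spec: constant 75 BPM, no SCRs, flat temperature."""
    return ps.EffectSpec(
        ibi_mean_s=0.8, ibi_lf_amp_s=0.0, ibi_hf_amp_s=0.0, ibi_noise_sd_s=0.0,
        ppg_noise_sd=0.0, eda_noise_sd_uS=0.0, scr_rate_per_min=0.0,
        scl_slope_uS_per_s=0.0, temp_slope_C_per_s=0.0, temp_noise_sd_C=0.0,
    )


@pytest.fixture
def small_cohort_config():
    return ps.CohortConfig(n_participants=2, phase_duration_s=60.0, fs=128.0, seed=11)


def ramp_recording(slope, duration_s=100.0, fs=32.0, offset=33.0, kind="temperature"):
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    return ps.ChannelRecording(offset + slope * t, fs, kind)
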