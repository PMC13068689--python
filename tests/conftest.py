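import numpy as np
import pytest

from pshwatch import episode_pipeline as pipe
from pshwatch import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table for a small synthetic cohort (6 PSH + 6 noPSH)."""
    return pipe.cohort_features(n_psh=6, n_nopsh=6, seed=11)


@pytest.fixture(scope="session")
def psh_episode():
    return sd.generate_rr_series(sd.default_psh_spec(seed=5))


@pytest.fixture(scope="session")
def nopsh_episode():
    return sd.generate_rr_series(sd.default_nopsh_spec(seed=5))


@pytest.fixture
def flat_spec():
    """Constant 60 b/min, no modulation: every RR is exactly 1000 ms."""
    return sd.EpisodeSpec(
        condition="noPSH",
        hr_baseline=60.0,
        hr_peak=60.0,
        duration=120.0,
        onset_time=60.0,
        band_amplitudes={b: 0.0 for b in sd.BANDS},
        band_slopes={b: 0.0 for b in sd.BANDS},
        noise_sd=0.0,
    )


def constant_beats(rr_s: float = 0.8, duration: float = 700.0):
    """Beat series with a perfectly constant RR interval."""
    from pshwatch.ecg_processing import BeatSeries

    times = np.arange(0.0, duration, rr_s)
    return BeatSeries(beat_times=times, source="synthetic")
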