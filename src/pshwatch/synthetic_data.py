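"""Synthetic PSH / noPSH episode generator.

Produces labeled 1800-s episodes (beat times, RR tachogram, optional ECG
waveform) whose statistical structure mirrors what the downstream analysis
assumes about autonomic storms: a sigmoidal heart-rate surge toward the
episode (97 -> 123 b/min for PSH vs 95 -> 100 for noPSH), band-limited
VLF/LF/HF oscillations whose amplitudes decay linearly in time (decaying
faster under PSH, with a relatively larger HF than LF loss), and a
white-vs-1/f modulation-noise mix that controls entropy/complexity.

Beats come from an integrate-and-fire (IPFM-style) model over an
instantaneous-rate function so that beat times, RR intervals, and ECG
placement stay mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ecg_processing import BeatSeries, ECGRecord

__all__ = [
    "EpisodeSpec",
    "SyntheticEpisode",
    "default_psh_spec",
    "default_nopsh_spec",
    "generate_rr_series",
    "generate_ecg",
    "generate_cohort",
]

BANDS = ("VLF", "LF", "HF")

#: Oscillator center frequencies (Hz), inside the canonical HRV bands.
DEFAULT_BAND_FREQS = {"VLF": 0.02, "LF": 0.06, "HF": 0.25}

#: Initial RR modulation amplitudes (seconds).
DEFAULT_BAND_AMPLITUDES = {"VLF": 0.045, "LF": 0.030, "HF": 0.025}

#: Amplitude decay (seconds of RR deviation per second).  PSH decays are
#: steeper in every band, |VLF| > |HF| > |LF| for PSH and |VLF| > |LF| > |HF|
#: for noPSH, and the HF *relative* loss over 1800 s exceeds the LF one under
#: PSH (0.94 vs 0.66) - the sign/ordering structure the trend analysis is
#: designed to detect.
PSH_BAND_SLOPES = {"VLF": -1.1e-5, "LF": -1.3e-5, "HF": -1.6e-5}
NOPSH_BAND_SLOPES = {"VLF": -7.0e-6, "LF": -7.0e-6, "HF": -8.0e-6}

#: Decay of the stochastic RR modulation (seconds of SD per second).  The
#: autonomic storm is a *decomplexification*: the irregular beat-to-beat
#: variability collapses while the deterministic surge dominates, which is
#: what drives entropy (CI_s, CI_l) down in PSH event windows.
PSH_NOISE_SLOPE = -8.7e-6
NOPSH_NOISE_SLOPE = -1.0e-6

#: The HR sigmoid is centered this many seconds before the annotated onset,
#: with this time constant, so the 10 minutes preceding onset already carry a
#: partial rise (Pre10 mean ~103 b/min for a 97->123 surge).
TRANSITION_LEAD_S = 120.0
TRANSITION_TAU_S = 150.0

_RR_CLAMP_S = (0.250, 2.000)  # physiological RR clamp, seconds


@dataclass
class EpisodeSpec:
    """Generative parameters for one synthetic episode.

    ``noise_mix`` blends the RR modulation noise between 1/f (0.0) and white
    (1.0); whiter noise raises sample entropy.  ``noise_sd`` is the standard
    deviation of that noise in seconds of RR deviation.
    """

    condition: str
    hr_baseline: float
    hr_peak: float
    duration: float = 1800.0
    onset_time: float = 1200.0
    band_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    band_slopes: dict = field(default_factory=lambda: dict(PSH_BAND_SLOPES))
    band_freqs: dict = field(default_factory=lambda: dict(DEFAULT_BAND_FREQS))
    noise_mix: float = 0.5
    noise_sd: float = 0.015
    noise_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("PSH", "noPSH"):
            raise ValueError("condition must be 'PSH' or 'noPSH'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.onset_time < self.duration:
            raise ValueError("onset_time must lie in [0, duration)")
        if self.hr_peak < self.hr_baseline:
            raise ValueError("hr_peak must be >= hr_baseline")
        for name in ("hr_baseline", "hr_peak"):
            hr = getattr(self, name)
            if not 20.0 <= hr <= 250.0:
                raise ValueError(f"{name}={hr} outside the plausible 20-250 b/min")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must lie in [0, 1]")

    def band_amplitude_at(self, band: str, t: np.ndarray) -> np.ndarray:
        """Linear amplitude envelope, clipped at zero."""
        a0 = self.band_amplitudes[band]
        return np.clip(a0 + self.band_slopes[band] * np.asarray(t), 0.0, None)

    def noise_sd_at(self, t: np.ndarray) -> np.ndarray:
        """Linearly decaying noise-SD envelope, clipped at zero."""
        return np.clip(self.noise_sd + self.noise_slope * np.asarray(t), 0.0, None)

    def heart_rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous heart rate (b/min): baseline plus sigmoid surge."""
        t = np.asarray(t, dtype=float)
        center = self.onset_time - TRANSITION_LEAD_S
        z = (t - center) / TRANSITION_TAU_S
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return self.hr_baseline + (self.hr_peak - self.hr_baseline) * sig


@dataclass
class SyntheticEpisode:
    beat_times: np.ndarray
    rr_intervals: np.ndarray  # milliseconds
    condition: str
    truth: EpisodeSpec
    ecg: ECGRecord | None = None

    def to_beat_series(self) -> BeatSeries:
        return BeatSeries(
            beat_times=self.beat_times, rr_ms=self.rr_intervals, source="synthetic"
        )


def default_psh_spec(seed: int = 0, **overrides) -> EpisodeSpec:
    """Default PSH episode: 97 -> 123 b/min surge, steep band-power decay,
    1/f-dominated modulation noise (low complexity)."""
    kw = dict(
        condition="PSH",
        hr_baseline=97.0,
        hr_peak=123.0,
        band_slopes=dict(PSH_BAND_SLOPES),
        noise_mix=0.2,
        noise_slope=PSH_NOISE_SLOPE,
        seed=seed,
    )
    kw.update(overrides)
    return EpisodeSpec(**kw)


def default_nopsh_spec(seed: int = 0, **overrides) -> EpisodeSpec:
    """Default noPSH episode: mild 95 -> 100 b/min rise, shallow decay,
    whiter modulation noise (preserved complexity)."""
    kw = dict(
        condition="noPSH",
        hr_baseline=95.0,
        hr_peak=100.0,
        band_slopes=dict(NOPSH_BAND_SLOPES),
        noise_mix=0.6,
        noise_slope=NOPSH_NOISE_SLOPE,
        seed=seed,
    )
    kw.update(overrides)
    return EpisodeSpec(**kw)


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (pink) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate_rr_series(spec: EpisodeSpec, grid_hz: float = 8.0) -> SyntheticEpisode:
    """Generate beats by integrate-and-fire over an instantaneous rate.

    The instantaneous RR period is the baseline 60/HR(t) plus the three
    band-limited oscillators and the mixed white/1-f noise, clamped to
    250-2000 ms; a beat fires each time the integrated rate crosses an
    integer.  Deterministic for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / grid_hz
    t = np.arange(0.0, spec.duration + dt, dt)

    period = 60.0 / spec.heart_rate_at(t)
    phases = rng.uniform(0, 2 * np.pi, size=len(BANDS))
    for phase, band in zip(phases, BANDS):
        amp = spec.band_amplitude_at(band, t)
        period = period + amp * np.sin(2 * np.pi * spec.band_freqs[band] * t + phase)

    if spec.noise_sd > 0:
        white = rng.standard_normal(t.size)
        pink = _one_over_f_noise(t.size, rng)
        mix = spec.noise_mix * white + (1.0 - spec.noise_mix) * pink
        sd = mix.std()
        if sd > 0:
            period = period + spec.noise_sd_at(t) * mix / sd

    period = np.clip(period, *_RR_CLAMP_S)
    rate = 1.0 / period  # beats per second

    # integrate-and-fire: beat k at the time the integral reaches k
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * dt)])
    n_beats = int(np.floor(integral[-1]))
    beat_times = np.interp(np.arange(n_beats + 1, dtype=float), integral, t)
    rr_ms = np.diff(beat_times) * 1000.0
    return SyntheticEpisode(
        beat_times=beat_times,
        rr_intervals=rr_ms,
        condition=spec.condition,
        truth=spec,
    )


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

#: Stereotyped P-QRS-T morphology: (amplitude mV, center offset s, width s)
_ECG_TEMPLATE = (
    (0.12, -0.190, 0.040),   # P
    (-0.10, -0.028, 0.010),  # Q
    (1.00, 0.000, 0.011),    # R
    (-0.18, 0.030, 0.012),   # S
    (0.28, 0.200, 0.055),    # T
)


def generate_ecg(
    beat_times: np.ndarray,
    fs: float = 250.0,
    snr_db: float = 30.0,
    duration: float | None = None,
    r_amp_modulation: tuple[float, float] | None = None,
    seed: int = 0,
) -> ECGRecord:
    """Synthesize a single-lead ECG with a P-QRS-T template at each beat.

    ``r_amp_modulation = (freq_hz, depth)`` sinusoidally modulates the
    R-wave amplitude, emulating respiratory amplitude modulation for EDR.
    Gaussian noise is added at ``snr_db`` relative to the clean waveform
    power.  An empty beat list yields a noise-only record flagged beatless.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size >= 2 and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if duration is None:
        duration = float(beat_times[-1] + 1.0) if beat_times.size else 10.0
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs
    signal = np.zeros(n)
    rng = np.random.default_rng(seed)

    for bt in beat_times:
        r_gain = 1.0
        if r_amp_modulation is not None:
            f_mod, depth = r_amp_modulation
            r_gain = 1.0 + depth * np.sin(2 * np.pi * f_mod * bt)
        for amp, offset, width in _ECG_TEMPLATE:
            if abs(offset) < 0.02:  # R wave carries the modulation
                amp = amp * r_gain
            lo = np.searchsorted(tgrid, bt + offset - 5 * width)
            hi = np.searchsorted(tgrid, bt + offset + 5 * width)
            seg = tgrid[lo:hi]
            signal[lo:hi] += amp * np.exp(-((seg - bt - offset) ** 2) / (2 * width**2))

    if beat_times.size:
        sig_power = np.mean(signal**2)
        noise_sd = np.sqrt(sig_power / 10 ** (snr_db / 10.0))
    else:
        noise_sd = 0.01
    samples = signal + rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(samples=samples, fs=fs, beatless=beat_times.size == 0)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Between-episode variability of the cohort draw (chosen once to emulate the
#: observed spread of ~12-15 b/min across events and a few-fold spread of raw
#: band powers; see the methods note).
COHORT_JITTER = {
    "hr_baseline_sd": 8.0,
    "hr_surge_sd": 6.0,
    "gain_sigma": 0.5,        # common lognormal gain on all RR modulation
    "amplitude_sigma": 0.3,   # per-band lognormal sigma on amplitudes
    "slope_sigma": 0.20,      # lognormal sigma on band decay timescales
    "noise_mix_sd": 0.05,
}


def _draw_spec(base: EpisodeSpec, rng: np.random.Generator, seed: int) -> EpisodeSpec:
    j = COHORT_JITTER
    hr_base = float(np.clip(base.hr_baseline + rng.normal(0, j["hr_baseline_sd"]), 40, 200))
    surge = base.hr_peak - base.hr_baseline
    hr_peak = hr_base + max(0.0, surge + rng.normal(0, j["hr_surge_sd"]))
    hr_peak = float(np.clip(hr_peak, hr_base, 240))
    # a common gain scales oscillators AND noise together: absolute band
    # powers spread heavily across episodes (the observed skewness of raw
    # powers) while the modulation *structure* - which entropy measures -
    # stays condition-typical
    gain = rng.lognormal(0.0, j["gain_sigma"])
    amp_factors = {
        b: gain * rng.lognormal(0.0, j["amplitude_sigma"])
        for b in base.band_amplitudes
    }
    amps = {b: a * amp_factors[b] for b, a in base.band_amplitudes.items()}
    # slopes scale with the drawn amplitude so each band's decay *timescale*
    # (amp/|slope|), not its endpoint, is what varies between episodes
    slopes = {
        b: s * amp_factors[b] * rng.lognormal(0.0, j["slope_sigma"])
        for b, s in base.band_slopes.items()
    }
    mix = float(np.clip(base.noise_mix + rng.normal(0, j["noise_mix_sd"]), 0, 1))
    return replace(
        base,
        hr_baseline=hr_base,
        hr_peak=hr_peak,
        band_amplitudes=amps,
        band_slopes=slopes,
        noise_mix=mix,
        noise_sd=base.noise_sd * gain,
        noise_slope=base.noise_slope * gain,
        seed=seed,
    )


def generate_cohort(
    n_psh: int, n_nopsh: int, seed: int = 0, with_ecg: bool = False
) -> tuple[list[SyntheticEpisode], pd.DataFrame]:
    """Draw a labeled cohort of synthetic episodes.

    Per-episode specs are drawn around the PSH / noPSH defaults.  Returns
    the episodes and a manifest table (episode_id, condition, seed, and the
    drawn heart-rate parameters).  Deterministic for a fixed seed.
    """
    if n_psh < 1 or n_nopsh < 1:
        raise ValueError("need at least one episode per condition")
    rng = np.random.default_rng(seed)
    episode_seeds = rng.integers(0, 2**31 - 1, size=n_psh + n_nopsh)
    episodes: list[SyntheticEpisode] = []
    rows = []
    for i in range(n_psh + n_nopsh):
        is_psh = i < n_psh
        base = default_psh_spec() if is_psh else default_nopsh_spec()
        spec = _draw_spec(base, rng, int(episode_seeds[i]))
        ep = generate_rr_series(spec)
        if with_ecg:
            ep.ecg = generate_ecg(ep.beat_times, seed=spec.seed)
        episodes.append(ep)
        rows.append(
            {
                "episode_id": f"{'psh' if is_psh else 'nopsh'}_{i:03d}",
                "condition": spec.condition,
                "seed": spec.seed,
                "hr_baseline": spec.hr_baseline,
                "hr_peak": spec.hr_peak,
                "onset_time": spec.onset_time,
            }
        )
    return episodes, pd.DataFrame(rows)


def write_episode_csv(episode: SyntheticEpisode, path) -> None:
    """Write the RR series as a two-column CSV (time_s, rr_ms)."""
    pd.DataFrame(
        {"time_s": episode.beat_times[1:], "rr_ms": episode.rr_intervals}
    ).to_csv(path, index=False)
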