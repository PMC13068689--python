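"""Morlet continuous-wavelet band-power time courses and linear trends.

The 4 Hz RR series (in seconds) is decomposed with an analytic Morlet
wavelet (center-frequency parameter omega0 = 6) over a log-spaced frequency
axis covering 0.0033-0.5 Hz at 12 voices per octave.  Squared moduli are
scaled to spectral density (s^2/Hz) so that a sinusoid of amplitude a
integrates to a^2/2 across frequency; band power time courses are the
per-time trapezoidal integrals over the VLF/LF/HF bands.  An ordinary
least-squares fit of band power on time summarizes each episode's gradual
autonomic decline (intercept, time coefficient, SE, F-ratio, p, R^2, and
the 95% CI of the slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
import statsmodels.api as sm

from .hrv_time_frequency import BAND_EDGES, UniformRRSeries

__all__ = [
    "TimeFrequencyMap",
    "BandPowerSeries",
    "TrendFit",
    "cwt_morlet",
    "band_power_timecourse",
    "ratio_timecourse",
    "linear_trend",
]

#: Morlet omega0 = 6 expressed as a PyWavelets complex Morlet:
#: psi(t) = (pi*B)^(-1/2) exp(2*pi*i*C*t) exp(-t^2/B) with B = 2 matching
#: the unit-variance Gaussian envelope and C = 6/(2*pi).
_MORLET_B = 2.0
_MORLET_C = 6.0 / (2.0 * np.pi)
_WAVELET = f"cmor{_MORLET_B}-{_MORLET_C:.12f}"


@dataclass
class TimeFrequencyMap:
    times: np.ndarray
    frequencies: np.ndarray          # Hz, descending or ascending per construction
    power: np.ndarray                # (n_freq, n_time), s^2/Hz
    coi_mask: np.ndarray             # True where outside the cone of influence

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class BandPowerSeries:
    band: str
    times: np.ndarray
    power: np.ndarray      # band-integrated spectral density, s^2
    valid: np.ndarray      # True where every band frequency is outside the COI


@dataclass
class TrendFit:
    intercept: float
    se_intercept: float
    time_coefficient: float      # per second
    se_time_coefficient: float
    f_ratio: float
    p_value: float
    r_squared: float
    ci95_low: float
    ci95_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.time_coefficient <= self.ci95_high):
            raise ValueError("CI must bracket the time coefficient")


def _frequency_axis(
    f_min: float = 0.0033, f_max: float = 0.5, voices_per_octave: int = 12
) -> np.ndarray:
    n_octaves = np.log2(f_max / f_min)
    n = int(np.ceil(n_octaves * voices_per_octave)) + 1
    return np.geomspace(f_min, f_max, n)


def cwt_morlet(
    series: UniformRRSeries,
    f_min: float = 0.0033,
    f_max: float = 0.5,
    voices_per_octave: int = 12,
    values_in: str = "ms",
) -> TimeFrequencyMap:
    """Continuous Morlet wavelet transform of the uniform RR series.

    The input is converted from ms to seconds (``values_in="s"`` skips the
    conversion) so power carries s^2/Hz.  When the series is shorter than
    two periods of the lowest frequency the VLF rows are flagged unreliable
    (warning) but still returned; the cone-of-influence mask marks, per
    frequency, the samples within one wavelet e-folding time of an edge.
    """
    if not series.detrended:
        raise ValueError("apply the quadratic detrend before the CWT")
    x = series.values / 1000.0 if values_in == "ms" else series.values.copy()
    dt = 1.0 / series.rate
    if series.duration < 2.0 / f_min:
        warnings.warn(
            "series shorter than two periods of the lowest frequency: "
            "VLF rows are unreliable",
            stacklevel=2,
        )

    freqs = _frequency_axis(f_min, f_max, voices_per_octave)[::-1]  # high->low
    scales = pywt.frequency2scale(_WAVELET, freqs * dt)
    coef, out_freqs = pywt.cwt(x, scales, _WAVELET, sampling_period=dt, method="fft")
    # |W|^2 * 2*dt*sqrt(2*pi*B): a sinusoid of amplitude a then integrates to
    # a^2/2 over frequency (verified numerically to ~1%)
    power = np.abs(coef) ** 2 * (2.0 * dt * np.sqrt(2.0 * np.pi * _MORLET_B))

    times = series.times
    rel_t = times - times[0]
    total = rel_t[-1]
    coi_mask = np.empty(power.shape, dtype=bool)
    for i, f in enumerate(out_freqs):
        efold = _MORLET_C * np.sqrt(_MORLET_B) / f  # envelope 1/e half-width, s
        coi_mask[i] = (rel_t >= efold) & (rel_t <= total - efold)
    return TimeFrequencyMap(
        times=times, frequencies=out_freqs, power=power, coi_mask=coi_mask
    )


def band_power_timecourse(tfmap: TimeFrequencyMap, band: str) -> BandPowerSeries:
    """Per-time trapezoidal integral of density over one band."""
    lo, hi = BAND_EDGES[band]
    mask = (tfmap.frequencies >= lo) & (
        tfmap.frequencies <= hi if band == "HF" else tfmap.frequencies < hi
    )
    if mask.sum() < 2:
        raise ValueError(f"band {band} not covered by the map's frequency axis")
    f = tfmap.frequencies[mask]
    order = np.argsort(f)
    power = np.trapezoid(tfmap.power[mask][order], f[order], axis=0)
    valid = tfmap.coi_mask[mask].all(axis=0)
    return BandPowerSeries(band=band, times=tfmap.times, power=power, valid=valid)


def ratio_timecourse(tfmap: TimeFrequencyMap) -> BandPowerSeries:
    """VLF / (LF + HF) ratio time course (slow-regulatory dominance)."""
    vlf = band_power_timecourse(tfmap, "VLF")
    lf = band_power_timecourse(tfmap, "LF")
    hf = band_power_timecourse(tfmap, "HF")
    denom = lf.power + hf.power
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, vlf.power / denom, np.nan)
    return BandPowerSeries(
        band="VLF/(LF+HF)",
        times=tfmap.times,
        power=ratio,
        valid=vlf.valid & lf.valid & hf.valid,
    )


def linear_trend(series: BandPowerSeries, use_coi: bool = True) -> TrendFit:
    """OLS of band power on time (seconds).

    By default only samples outside the cone of influence enter the fit
    (``use_coi=False`` restores the naive full-window fit).  Inference uses
    the t distribution with n-2 degrees of freedom; serial correlation of
    the wavelet power is deliberately ignored, matching the conventional
    presentation of such trend tables.
    """
    keep = series.valid if use_coi else np.ones(series.times.size, dtype=bool)
    keep = keep & np.isfinite(series.power)
    t = series.times[keep]
    y = series.power[keep]
    if t.size < 3:
        raise ValueError("need at least 3 usable time points")
    if np.ptp(t) == 0:
        raise ValueError("zero-variance time vector")

    X = sm.add_constant(t)
    fit = sm.OLS(y, X).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:  # constant series: slope 0, no explained variance
        return TrendFit(
            intercept=float(y.mean()),
            se_intercept=0.0,
            time_coefficient=0.0,
            se_time_coefficient=0.0,
            f_ratio=0.0,
            p_value=1.0,
            r_squared=0.0,
            ci95_low=0.0,
            ci95_high=0.0,
            n=int(t.size),
        )
    ci = fit.conf_int(alpha=0.05)
    f_ratio = float(fit.fvalue) if np.isfinite(fit.fvalue) else float("inf")
    p_value = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 0.0
    return TrendFit(
        intercept=float(fit.params[0]),
        se_intercept=float(fit.bse[0]),
        time_coefficient=float(fit.params[1]),
        se_time_coefficient=float(fit.bse[1]),
        f_ratio=f_ratio,
        p_value=p_value,
        r_squared=float(fit.rsquared),
        ci95_low=float(ci[1, 0]),
        ci95_high=float(ci[1, 1]),
        n=int(t.size),
    )
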