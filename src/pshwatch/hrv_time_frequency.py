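"""Time-domain and Welch frequency-domain HRV measures for a 600-s window.

The RR tachogram is cubic-spline resampled to a uniform 4 Hz grid,
quadratically detrended, and its power spectral density estimated with
Welch's method (150-s Hann segments, 50% overlap).  Band powers are
integrated over the canonical HRV bands: VLF 0.0033-0.04 Hz, LF
0.04-0.15 Hz, HF 0.15-0.5 Hz; natural logs and the LF/HF and VLF/(LF+HF)
ratios are reported alongside mean/max heart rate and SDNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .ecg_processing import BeatSeries

__all__ = [
    "BAND_EDGES",
    "UniformRRSeries",
    "TimeDomainSummary",
    "SpectralSummary",
    "PSD",
    "resample_uniform",
    "detrend_quadratic",
    "welch_psd",
    "band_powers",
    "time_domain",
]

#: Band edges in Hz; half-open [low, high) except HF which closes at 0.5 Hz.
BAND_EDGES = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.5)}


@dataclass
class UniformRRSeries:
    """RR values (ms) on a uniform grid."""

    values: np.ndarray
    rate: float = 4.0
    t0: float = 0.0
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass
class TimeDomainSummary:
    mean_hr: float          # b/min
    max_hr: float           # b/min, max of 10-s rolling-mean HR
    sdnn: float             # ms, population SD of accepted intervals
    max_hr_beat: float      # b/min, raw per-beat maximum (reported alongside)

    def __post_init__(self) -> None:
        if self.sdnn < 0:
            raise ValueError("sdnn must be nonnegative")


@dataclass
class SpectralSummary:
    power_vlf: float
    power_lf: float
    power_hf: float
    power_total: float
    ln_vlf: float | None
    ln_lf: float | None
    ln_hf: float | None
    ln_total: float | None
    lf_hf_ratio: float
    vlf_over_lf_plus_hf: float


@dataclass
class PSD:
    freqs: np.ndarray
    density: np.ndarray  # ms^2/Hz
    units: str = "ms^2/Hz"


def resample_uniform(beats: BeatSeries, rate: float = 4.0) -> UniformRRSeries:
    """Cubic-spline interpolation of RR vs beat time onto a uniform grid.

    The grid spans [first beat, last beat].  RR at beat time t[i+1] is the
    interval ending there.
    """
    if beats.n_beats < 4:
        raise ValueError("resampling needs at least 4 beats (cubic spline order)")
    t = beats.beat_times[1:]
    if t[-1] - beats.beat_times[0] < 10.0:
        raise ValueError("resampling needs at least 10 s of beats")
    spline = CubicSpline(t, beats.rr_ms)
    grid = np.arange(t[0], t[-1] + 0.5 / rate, 1.0 / rate)
    grid = grid[grid <= t[-1]]
    return UniformRRSeries(values=spline(grid), rate=rate, t0=grid[0])


def detrend_quadratic(series: UniformRRSeries) -> UniformRRSeries:
    """Remove the least-squares quadratic-in-time trend."""
    if series.values.size < 3:
        raise ValueError("need at least 3 samples to fit a quadratic")
    t = series.times - series.times[0]
    coeffs = np.polynomial.polynomial.polyfit(t, series.values, 2)
    residual = series.values - np.polynomial.polynomial.polyval(t, coeffs)
    return UniformRRSeries(
        values=residual, rate=series.rate, t0=series.t0, detrended=True
    )


def welch_psd(series: UniformRRSeries, window_s: float = 150.0) -> PSD:
    """Welch PSD with Hann segments of ``window_s`` seconds, 50% overlap."""
    if not series.detrended:
        raise ValueError("detrend the series before spectral estimation")
    if series.duration < window_s:
        raise ValueError(
            f"series ({series.duration:.0f} s) shorter than the Welch window "
            f"({window_s:.0f} s); use a shorter window"
        )
    nperseg = int(round(window_s * series.rate))
    freqs, density = welch(
        series.values,
        fs=series.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return PSD(freqs=freqs, density=density)


def _integrate_band(psd: PSD, lo: float, hi: float, closed_hi: bool) -> float:
    if closed_hi:
        mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    else:
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd.density[mask], psd.freqs[mask]))


#: Band powers below this (ms^2) are numerically indistinguishable from zero
#: (e.g. the residual of an exactly-detrended constant series).
_POWER_FLOOR = 1e-12


def _safe_ln(power: float) -> float | None:
    if power < _POWER_FLOOR:
        warnings.warn("zero band power: ln reported as missing", stacklevel=3)
        return None
    return float(np.log(power))


def band_powers(psd: PSD) -> SpectralSummary:
    """Integrate the PSD over the VLF/LF/HF bands (trapezoidal rule)."""
    if psd.freqs[-1] < 0.5:
        raise ValueError("PSD must cover [0, 0.5] Hz")
    p = {
        band: _integrate_band(psd, lo, hi, closed_hi=(band == "HF"))
        for band, (lo, hi) in BAND_EDGES.items()
    }
    total = _integrate_band(psd, 0.0, 0.5, closed_hi=True)
    lf_hf = p["LF"] / p["HF"] if p["HF"] > 0 else np.nan
    vlf_ratio = p["VLF"] / (p["LF"] + p["HF"]) if p["LF"] + p["HF"] > 0 else np.nan
    return SpectralSummary(
        power_vlf=p["VLF"],
        power_lf=p["LF"],
        power_hf=p["HF"],
        power_total=total,
        ln_vlf=_safe_ln(p["VLF"]),
        ln_lf=_safe_ln(p["LF"]),
        ln_hf=_safe_ln(p["HF"]),
        ln_total=_safe_ln(total),
        lf_hf_ratio=lf_hf,
        vlf_over_lf_plus_hf=vlf_ratio,
    )


def time_domain(
    beats: BeatSeries, rolling_s: float = 10.0
) -> TimeDomainSummary | None:
    """Mean/max heart rate and SDNN for one window of beats.

    max_hr is the maximum of the 10-s rolling-mean heart rate (suppressing
    single-beat spikes); the raw per-beat maximum is reported separately.
    SDNN uses accepted (non-flagged) intervals only.
    """
    rr = beats.accepted_rr()
    if rr.size < 10:
        warnings.warn("fewer than 10 accepted intervals: no time-domain summary",
                      stacklevel=2)
        return None
    mean_hr = 60000.0 / float(np.mean(rr))
    sdnn = float(np.std(rr, ddof=0))

    hr_inst = 60000.0 / beats.rr_ms
    mids = (beats.beat_times[:-1] + beats.beat_times[1:]) / 2.0
    grid = np.arange(mids[0], mids[-1], 1.0)
    if grid.size >= rolling_s:
        hr_grid = np.interp(grid, mids, hr_inst)
        kernel = np.ones(int(rolling_s)) / rolling_s
        rolled = np.convolve(hr_grid, kernel, mode="valid")
        max_hr = float(rolled.max())
    else:
        max_hr = float(hr_inst.max())
    return TimeDomainSummary(
        mean_hr=mean_hr,
        max_hr=max(max_hr, mean_hr),
        sdnn=sdnn,
        max_hr_beat=float(hr_inst.max()),
    )
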