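"""Raw ECG to clean RR tachogram.

Implements the preprocessing stage of the episode pipeline: Pan-Tompkins
R-peak detection, local-median artifact flagging with cubic-spline
replacement, and an ECG-derived respiration (EDR) estimate based on
beat-to-beat R-wave amplitude modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks, welch

__all__ = [
    "ECGRecord",
    "BeatSeries",
    "CorrectionReport",
    "detect_r_peaks",
    "correct_artifacts",
    "derive_respiration",
]


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage in mV.
    fs : float
        Sampling rate in Hz (the recording hardware emulated here samples
        at 250 Hz).
    start_time : float
        Time of the first sample in seconds.
    beatless : bool
        Set by the synthetic generator when the record was produced from an
        empty beat list (noise only).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    beatless: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2:
            raise ValueError("an ECG record needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """R-peak times and the RR tachogram derived from them.

    ``rr_ms[i]`` is the interval between ``beat_times[i]`` and
    ``beat_times[i+1]`` in milliseconds.  ``corrected_flags`` marks intervals
    replaced (or excluded) by artifact correction; ``source`` records whether
    the beats were detected from ECG, read from annotations, or generated.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray = None
    corrected_flags: np.ndarray = None
    source: str = "detected"
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.rr_ms is None:
            self.rr_ms = np.diff(self.beat_times) * 1000.0
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.corrected_flags is None:
            self.corrected_flags = np.zeros(self.rr_ms.size, dtype=bool)
        self.corrected_flags = np.asarray(self.corrected_flags, dtype=bool)
        if self.beat_times.size >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.corrected_flags.size != self.rr_ms.size:
            raise ValueError("corrected_flags must match rr_ms length")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    def accepted_rr(self) -> np.ndarray:
        """RR intervals not flagged by artifact correction."""
        return self.rr_ms[~self.corrected_flags]


@dataclass
class CorrectionReport:
    n_detected_artifacts: int
    fraction_corrected: float
    method: str
    low_quality: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_corrected <= 1.0:
            raise ValueError("fraction_corrected must lie in [0, 1]")


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(
    ecg: ECGRecord,
    refractory_s: float = 0.200,
    integration_window_s: float = 0.150,
    refine_window_s: float = 0.025,
) -> np.ndarray:
    """Detect R-peak times with the Pan-Tompkins cascade.

    Stages: 5-15 Hz band-pass, differentiation, squaring, 150-ms moving
    window integration, adaptive dual-threshold peak picking with
    search-back, 200-ms refractory period.  Candidates are refined to the
    local maximum of the raw signal within +/-25 ms, which also makes the
    output invariant to a constant voltage offset.

    Returns an array of peak times (seconds); empty (with a warning) for a
    flat or beatless signal.
    """
    if ecg.duration < 10.0:
        raise ValueError("need at least 10 s of ECG")
    if ecg.fs < 100.0:
        raise ValueError("need fs >= 100 Hz for QRS detection")

    fs = ecg.fs
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) < 1e-9:
        warnings.warn("flat ECG signal: no beats detected", stacklevel=2)
        return np.array([])

    b, a = butter(2, [5.0 / (fs / 2), 15.0 / (fs / 2)], btype="band")
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(integration_window_s * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(refractory_s * fs))
    cand, _ = find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return np.array([])

    # Adaptive dual thresholds with search-back (classic running estimates
    # of signal and noise peak levels).
    spki = float(np.percentile(mwi[cand], 75))
    npki = float(np.percentile(mwi[cand], 25)) * 0.5
    accepted: list[int] = []
    noise_peaks: list[int] = []
    rr_history: list[float] = []
    for idx in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[idx] > thr1:
            accepted.append(idx)
            spki = 0.125 * mwi[idx] + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append(accepted[-1] - accepted[-2])
                rr_history = rr_history[-8:]
        else:
            noise_peaks.append(idx)
            npki = 0.125 * mwi[idx] + 0.875 * npki
        # search-back: if too long since the last beat, accept the largest
        # missed candidate above the lower threshold
        if rr_history and accepted:
            rr_avg = float(np.mean(rr_history))
            if idx - accepted[-1] > 1.66 * rr_avg and noise_peaks:
                missed = [j for j in noise_peaks if accepted[-1] < j < idx]
                if missed:
                    thr2 = 0.5 * (npki + 0.25 * (spki - npki))
                    best = max(missed, key=lambda j: mwi[j])
                    if mwi[best] > thr2 and best - accepted[-1] >= refractory:
                        accepted.append(best)
                        accepted.sort()
                        spki = 0.25 * mwi[best] + 0.75 * spki

    if not accepted:
        warnings.warn("no QRS candidates passed thresholding", stacklevel=2)
        return np.array([])

    # refine to the raw-signal local maximum
    half = max(1, int(round(refine_window_s * fs)))
    refined = []
    for idx in sorted(set(accepted)):
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(ecg.samples[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(idx)
    return ecg.start_time + np.asarray(keep) / fs


# ---------------------------------------------------------------------------
# Artifact correction
# ---------------------------------------------------------------------------

def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median, shrinking the window at the edges."""
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def correct_artifacts(
    beats: BeatSeries,
    threshold: float = 0.25,
    window: int = 11,
    mode: str = "interpolate",
    low_quality_fraction: float = 0.20,
) -> tuple[BeatSeries, CorrectionReport]:
    """Flag and repair ectopic / artifact RR intervals.

    An interval deviating from its local median (centered window of
    ``window`` intervals) by more than ``threshold`` (fraction) is flagged.
    In ``interpolate`` mode flagged intervals are replaced by cubic-spline
    values interpolated over accepted intervals, then each contiguous
    flagged run is rescaled so its RR sum equals the original run duration:
    accepted beat times are preserved exactly and the total duration is
    conserved.  In ``exclude`` mode values are left in place and the flags
    mark intervals to be skipped by time-domain statistics.

    Series with more than ``low_quality_fraction`` of intervals flagged are
    marked low quality but still processed.
    """
    rr = beats.rr_ms
    if rr.size < 10:
        raise ValueError("need at least 10 RR intervals")
    med = _rolling_median(rr, window)
    flags = np.abs(rr - med) / med > threshold
    frac = float(np.mean(flags))
    low_q = frac > low_quality_fraction
    if low_q:
        warnings.warn(
            f"{frac:.0%} of intervals flagged: series marked low quality",
            stacklevel=2,
        )

    new_rr = rr.copy()
    if mode == "interpolate" and flags.any() and (~flags).sum() >= 2:
        idx = np.arange(rr.size)
        spline = CubicSpline(idx[~flags], rr[~flags])
        new_rr[flags] = spline(idx[flags])
        # rescale each contiguous flagged run to conserve its duration
        run_start = None
        for i in range(rr.size + 1):
            inside = i < rr.size and flags[i]
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                sl = slice(run_start, i)
                orig = rr[sl].sum()
                repl = new_rr[sl].sum()
                if repl > 0:
                    new_rr[sl] *= orig / repl
                run_start = None
        beat_times = beats.beat_times[0] + np.concatenate(
            [[0.0], np.cumsum(new_rr) / 1000.0]
        )
    elif mode == "exclude":
        beat_times = beats.beat_times
    else:
        beat_times = beats.beat_times

    corrected = BeatSeries(
        beat_times=beat_times,
        rr_ms=new_rr,
        corrected_flags=flags,
        source=beats.source,
        low_quality=low_q,
    )
    report = CorrectionReport(
        n_detected_artifacts=int(flags.sum()),
        fraction_corrected=frac if mode == "interpolate" else 0.0,
        method=f"local-median({window}) {threshold:.0%} rule, {mode}",
        low_quality=low_q,
    )
    return corrected, report


# ---------------------------------------------------------------------------
# ECG-derived respiration
# ---------------------------------------------------------------------------

def derive_respiration(
    ecg: ECGRecord,
    beats: BeatSeries,
    band: tuple[float, float] = (0.1, 0.7),
    resample_hz: float = 4.0,
    peak_over_floor: float = 5.0,
) -> float | None:
    """Estimate respiratory rate (breaths/min) from R-wave amplitude EDR.

    The per-beat R amplitude series is spline-resampled to 4 Hz and the
    dominant spectral peak inside ``band`` is reported in breaths/min.
    Returns None (with a warning) when no peak rises ``peak_over_floor``
    times above the median spectral level, e.g. for constant-amplitude ECG.
    """
    if beats.n_beats < 4:
        raise ValueError("need detected beats to derive respiration")
    if beats.beat_times[-1] - beats.beat_times[0] < 60.0:
        raise ValueError("need at least 60 s of beats for EDR")

    half = max(1, int(round(0.025 * ecg.fs)))
    idx = np.round((beats.beat_times - ecg.start_time) * ecg.fs).astype(int)
    amps = np.array(
        [
            ecg.samples[max(0, i - half): min(ecg.samples.size, i + half + 1)].max()
            for i in idx
        ]
    )
    t = beats.beat_times
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    edr = CubicSpline(t, amps)(grid)
    edr = edr - edr.mean()

    nper = min(edr.size, int(round(60 * resample_hz)))
    freqs, psd = welch(edr, fs=resample_hz, nperseg=nper)
    search = (freqs >= 0.05) & (freqs <= 1.0)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    if not inband.any() or psd[search].size == 0:
        warnings.warn("no usable EDR spectrum", stacklevel=2)
        return None
    floor = np.median(psd[search])
    peak_idx = np.argmax(psd[inband])
    peak_power = psd[inband][peak_idx]
    if floor <= 0 or peak_power < peak_over_floor * floor:
        warnings.warn("no respiratory peak above the noise floor", stacklevel=2)
        return None
    return float(freqs[inband][peak_idx] * 60.0)
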