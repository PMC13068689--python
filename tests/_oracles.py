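"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths of the package: sample entropy by
an O(N^2) double loop, OLS by explicit normal equations, band power by a
plain FFT periodogram, and peak matching by greedy nearest-neighbor
assignment.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by exhaustive pairwise template comparison."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def count(length: int) -> int:
        tpl = [x[i: i + length] for i in range(n - m)]
        c = 0
        for i in range(len(tpl)):
            for j in range(i + 1, len(tpl)):
                if np.max(np.abs(tpl[i] - tpl[j])) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def ols_normal_equations(t, y, alpha: float = 0.05) -> dict:
    """Simple linear regression via the textbook normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - intercept - slope * t
    sse = np.sum(resid**2)
    sst = np.sum((y - ybar) ** 2)
    sigma2 = sse / (n - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / n + tbar**2 / sxx))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    if se_slope > 0:
        t_stat = slope / se_slope
        f_ratio = t_stat**2
        p = 2 * stats.t.sf(abs(t_stat), n - 2)
    else:
        f_ratio, p = float("inf"), 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    return {
        "intercept": intercept,
        "se_intercept": se_intercept,
        "slope": slope,
        "se_slope": se_slope,
        "f_ratio": f_ratio,
        "p_value": p,
        "r_squared": r2,
        "ci95": (slope - tcrit * se_slope, slope + tcrit * se_slope),
    }


def t_statistic_independent(x, y) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(t), nx + ny - 2


def t_statistic_paired(x, y) -> tuple[float, int]:
    d = np.asarray(x, float) - np.asarray(y, float)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    return float(t), d.size - 1


def fft_band_power(x, fs: float, lo: float, hi: float) -> float:
    """Band power from a plain rectangular-window FFT periodogram."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2 / (x.size * fs)
    spec[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    return float(spec[mask].sum() * fs / x.size)


def fft_peak_frequency(x, fs: float) -> float:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    return float(freqs[np.argmax(spec)])


def match_f1(truth, detected, tol_s: float = 0.020) -> float:
    """Detection F1 with greedy one-to-one matching at a time tolerance."""
    truth = np.asarray(truth, float)
    detected = np.asarray(detected, float)
    if detected.size == 0 or truth.size == 0:
        return 0.0
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        d = np.abs(detected - t)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            tp += 1
            used[i] = True
    precision = tp / detected.size
    sensitivity = tp / truth.size
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)
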