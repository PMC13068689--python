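"""Cohort orchestration: windowing, feature assembly, statistics, PSH-AM.

Each annotated episode is split into three adjacent 600-s windows: Pre20
[onset-1200, onset-600), Pre10 [onset-600, onset), and Event
[onset, onset+600).  Per window the pipeline collects the time-domain,
Welch-spectral, and multiscale-entropy features; group contrasts use
Shapiro-Wilk normality checks and paired / independent t-tests under a
Bonferroni-corrected alpha (0.05/44 by default, the planned-comparison
budget).  A small utility scores the PSH Assessment Measure (Clinical
Features Scale + Diagnosis Likelihood Tool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import hrv_complexity as cx
from . import hrv_time_frequency as tf
from .ecg_processing import BeatSeries, correct_artifacts
from .synthetic_data import SyntheticEpisode, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOW_NAMES",
    "EpisodeWindows",
    "FeatureVector",
    "GroupComparison",
    "PSHAMScore",
    "PipelineConfig",
    "segment_windows",
    "extract_features",
    "cohort_features",
    "compare_conditions",
    "standard_comparisons",
    "psh_am_score",
]

WINDOW_NAMES = ("Pre20", "Pre10", "Event")
WINDOW_S = 600.0

FEATURE_COLUMNS = [
    "mean_hr",
    "max_hr",
    "sdnn",
    "ln_vlf",
    "ln_lf",
    "ln_hf",
    "lf_hf_ratio",
    "vlf_over_lf_plus_hf",
    "ci_short",
    "ci_long",
]


@dataclass
class EpisodeWindows:
    onset: float
    pre20: tuple[float, float]
    pre10: tuple[float, float]
    event: tuple[float, float]

    @classmethod
    def around(cls, onset: float) -> "EpisodeWindows":
        return cls(
            onset=onset,
            pre20=(onset - 2 * WINDOW_S, onset - WINDOW_S),
            pre10=(onset - WINDOW_S, onset),
            event=(onset, onset + WINDOW_S),
        )

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {"Pre20": self.pre20, "Pre10": self.pre10, "Event": self.event}


@dataclass
class FeatureVector:
    episode_id: str
    window: str
    condition: str
    mean_hr: float
    max_hr: float
    sdnn: float
    ln_vlf: float
    ln_lf: float
    ln_hf: float
    lf_hf_ratio: float
    vlf_over_lf_plus_hf: float
    ci_short: float
    ci_long: float
    etiology: str | None = None
    raw_power_vlf: float = np.nan
    raw_power_lf: float = np.nan
    raw_power_hf: float = np.nan


@dataclass
class GroupComparison:
    measure: str
    design: str                 # "paired" | "independent"
    t_statistic: float
    df: int
    p_value: float
    effect_r2: float            # t^2 / (t^2 + df)
    shapiro_p: float
    alpha_bonferroni: float
    significant: bool
    normal: bool


@dataclass
class PSHAMScore:
    cfs_items: list[int]
    dlt_items: list[int]
    cfs_total: int
    dlt_total: int
    combined: int
    category: str
    severe_features: bool


@dataclass
class PipelineConfig:
    """Tunable analysis parameters, loadable from YAML."""

    window_s: float = WINDOW_S
    resample_hz: float = 4.0
    welch_window_s: float = 150.0
    mse_m: int = 2
    mse_r_fraction: float = 0.2
    mse_max_scale: int = 10
    artifact_threshold: float = 0.25
    bonferroni_divisor: int = 44
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def segment_windows(
    beats: BeatSeries, onset: float, tolerance_s: float = 2.0
) -> tuple[EpisodeWindows, dict[str, BeatSeries]]:
    """Split a beat series into the three 600-s analysis windows.

    Beats on a window boundary go to the later window.  Raises when the
    recording does not cover [onset-1200, onset+600] (up to one maximal RR
    interval of slack at each end).
    """
    win = EpisodeWindows.around(onset)
    t0, t1 = win.pre20[0], win.event[1]
    if beats.beat_times[0] > t0 + tolerance_s or beats.beat_times[-1] < t1 - tolerance_s:
        raise ValueError(
            f"recording [{beats.beat_times[0]:.1f}, {beats.beat_times[-1]:.1f}] s "
            f"does not cover the required span [{t0:.1f}, {t1:.1f}] s"
        )
    out: dict[str, BeatSeries] = {}
    for name, (lo, hi) in win.intervals().items():
        mask = (beats.beat_times >= lo) & (beats.beat_times < hi)
        idx = np.where(mask)[0]
        # keep the intervals whose both endpoint beats fall in the window
        rr_idx = idx[:-1] if idx.size else idx
        out[name] = BeatSeries(
            beat_times=beats.beat_times[mask],
            rr_ms=beats.rr_ms[rr_idx],
            corrected_flags=beats.corrected_flags[rr_idx],
            source=beats.source,
            low_quality=beats.low_quality,
        )
    return win, out


def extract_features(
    episode_id: str,
    condition: str,
    window_name: str,
    beats: BeatSeries,
    config: PipelineConfig | None = None,
    etiology: str | None = None,
) -> FeatureVector:
    """Assemble the per-window feature vector.

    Spectral features come from the 4 Hz resampled, quadratically detrended
    series analyzed with Welch's method; entropy features from the
    beat-domain RR series.  Missing upstream values propagate as NaN.
    """
    config = config or PipelineConfig()
    td = tf.time_domain(beats)
    uniform = tf.resample_uniform(beats, rate=config.resample_hz)
    detrended = tf.detrend_quadratic(uniform)
    spectral = tf.band_powers(tf.welch_psd(detrended, config.welch_window_s))
    profile = cx.multiscale_entropy(
        beats.accepted_rr(),
        m=config.mse_m,
        r_fraction=config.mse_r_fraction,
        max_scale=config.mse_max_scale,
    )
    ci = cx.complexity_indices(profile)

    def _or_nan(v):
        return np.nan if v is None else v

    return FeatureVector(
        episode_id=episode_id,
        window=window_name,
        condition=condition,
        mean_hr=td.mean_hr if td else np.nan,
        max_hr=td.max_hr if td else np.nan,
        sdnn=td.sdnn if td else np.nan,
        ln_vlf=_or_nan(spectral.ln_vlf),
        ln_lf=_or_nan(spectral.ln_lf),
        ln_hf=_or_nan(spectral.ln_hf),
        lf_hf_ratio=spectral.lf_hf_ratio,
        vlf_over_lf_plus_hf=spectral.vlf_over_lf_plus_hf,
        ci_short=ci.ci_short,
        ci_long=ci.ci_long,
        etiology=etiology,
        raw_power_vlf=spectral.power_vlf,
        raw_power_lf=spectral.power_lf,
        raw_power_hf=spectral.power_hf,
    )


def episode_features(
    episode: SyntheticEpisode,
    episode_id: str,
    config: PipelineConfig | None = None,
    correct: bool = False,
) -> list[FeatureVector]:
    """Window an episode at its annotated onset and extract all features."""
    config = config or PipelineConfig()
    beats = episode.to_beat_series()
    if correct:
        beats, _ = correct_artifacts(beats, threshold=config.artifact_threshold)
    _, windows = segment_windows(beats, episode.truth.onset_time)
    return [
        extract_features(episode_id, episode.condition, name, wbeats, config)
        for name, wbeats in windows.items()
    ]


def cohort_features(
    episodes: list[SyntheticEpisode] | None = None,
    manifest: pd.DataFrame | None = None,
    n_psh: int = 24,
    n_nopsh: int = 24,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per (episode, window).

    Generates a default synthetic cohort when no episodes are passed.  Logs
    the skewness of the raw band powers (the motivation for the ln
    transform of spectral features).
    """
    config = config or PipelineConfig(seed=seed)
    if episodes is None:
        episodes, manifest = generate_cohort(n_psh, n_nopsh, seed=seed)
    ids = (
        manifest["episode_id"].tolist()
        if manifest is not None
        else [f"ep_{i:03d}" for i in range(len(episodes))]
    )
    rows = []
    for ep, eid in zip(episodes, ids):
        rows.extend(vars(fv) for fv in episode_features(ep, eid, config))
    df = pd.DataFrame(rows)
    for band in ("vlf", "lf", "hf"):
        sk = stats.skew(df[f"raw_power_{band}"].dropna())
        logger.info("raw %s band power skewness: %.2f", band.upper(), sk)
    return df


def compare_conditions(
    features: pd.DataFrame,
    measure: str,
    design: str,
    groups: tuple[str, str],
    group_col: str = "condition",
    window: str | None = None,
    bonferroni_divisor: int = 44,
) -> GroupComparison:
    """Two-sided t-test (paired or independent) for one HRV measure.

    ``groups`` names the two levels of ``group_col`` being contrasted (two
    conditions within a window, or two windows within a condition when
    ``group_col="window"``).  Paired designs match rows by episode_id.
    Shapiro-Wilk runs on the paired differences (paired) or pooled groups
    (independent); non-normal data are flagged but the t-test is still
    reported.
    """
    df = features
    if window is not None:
        df = df[df["window"] == window]
    a = df[df[group_col] == groups[0]].set_index("episode_id")[measure]
    b = df[df[group_col] == groups[1]].set_index("episode_id")[measure]
    if design == "paired":
        common = a.index.intersection(b.index)
        if len(common) < 3:
            raise ValueError("paired design needs >= 3 matched episodes")
        x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
        shapiro_p = float(stats.shapiro(x - y).pvalue)
        t_stat, p = stats.ttest_rel(x, y)
        df_t = len(common) - 1
    elif design == "independent":
        x, y = a.to_numpy(), b.to_numpy()
        if min(x.size, y.size) < 3:
            raise ValueError("need >= 3 observations per group")
        shapiro_p = float(min(stats.shapiro(x).pvalue, stats.shapiro(y).pvalue))
        t_stat, p = stats.ttest_ind(x, y)
        df_t = x.size + y.size - 2
    else:
        raise ValueError("design must be 'paired' or 'independent'")

    t_stat = float(t_stat)
    p = float(p)
    alpha = 0.05 / bonferroni_divisor
    r2 = t_stat**2 / (t_stat**2 + df_t) if df_t > 0 else 0.0
    return GroupComparison(
        measure=measure,
        design=design,
        t_statistic=t_stat,
        df=df_t,
        p_value=p,
        effect_r2=float(r2),
        shapiro_p=shapiro_p,
        alpha_bonferroni=alpha,
        significant=bool(p < alpha),
        normal=bool(shapiro_p >= 0.05),
    )


def standard_comparisons(
    features: pd.DataFrame, bonferroni_divisor: int = 44
) -> pd.DataFrame:
    """The planned contrast battery: PSH-vs-noPSH per window (independent)
    and adjacent-window pairs within each condition (paired), for every
    feature column."""
    rows = []
    for measure in FEATURE_COLUMNS:
        for window in WINDOW_NAMES:
            gc = compare_conditions(
                features, measure, "independent", ("PSH", "noPSH"),
                window=window, bonferroni_divisor=bonferroni_divisor,
            )
            rows.append({"window": window, "contrast": "PSH-vs-noPSH", **vars(gc)})
        for cond in ("PSH", "noPSH"):
            sub = features[features["condition"] == cond]
            for w1, w2 in (("Pre20", "Pre10"), ("Pre10", "Event")):
                gc = compare_conditions(
                    sub, measure, "paired", (w1, w2), group_col="window",
                    bonferroni_divisor=bonferroni_divisor,
                )
                rows.append(
                    {"window": f"{w1}-vs-{w2}", "contrast": cond, **vars(gc)}
                )
    return pd.DataFrame(rows)


def psh_am_score(cfs_items, dlt_items) -> PSHAMScore:
    """Score the PSH Assessment Measure.

    Six Clinical Features Scale items rated 0-3 (heart rate, respiratory
    rate, systolic blood pressure, temperature, sweating, posturing) and
    eleven binary Diagnosis Likelihood Tool items.  CFS totals above 13
    flag severe features; a combined score of 19 or more is categorized
    "probable PSH" (the instrument's higher scores cannot be less likely),
    8-18 "possible", below 8 "unlikely".
    """
    cfs = list(cfs_items)
    dlt = list(dlt_items)
    if len(cfs) != 6:
        raise ValueError("the Clinical Features Scale has exactly 6 items")
    if len(dlt) != 11:
        raise ValueError("the Diagnosis Likelihood Tool has exactly 11 items")
    for i, v in enumerate(cfs):
        if v not in (0, 1, 2, 3):
            raise ValueError(f"CFS item {i} = {v!r} outside 0-3")
    for i, v in enumerate(dlt):
        if v not in (0, 1):
            raise ValueError(f"DLT item {i} = {v!r} not binary")
    cfs_total = sum(cfs)
    dlt_total = sum(dlt)
    combined = cfs_total + dlt_total
    if combined >= 19:
        category = "probable PSH"
    elif combined >= 8:
        category = "possible PSH"
    else:
        category = "unlikely"
    return PSHAMScore(
        cfs_items=cfs,
        dlt_items=dlt,
        cfs_total=cfs_total,
        dlt_total=dlt_total,
        combined=combined,
        category=category,
        severe_features=cfs_total > 13,
    )
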