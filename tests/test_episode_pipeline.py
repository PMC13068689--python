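import subprocess

import numpy as np
import pandas as pd
import pytest

from pshwatch import episode_pipeline as pipe
from pshwatch import synthetic_data as sd
from pshwatch.ecg_processing import BeatSeries

from _oracles import t_statistic_independent, t_statistic_paired
from conftest import constant_beats


class TestSegmentWindows:
    def test_standard_windows(self, psh_episode):
        windows, subsets = pipe.segment_windows(
            psh_episode.to_beat_series(), onset=1200.0
        )
        assert windows.pre20 == (0.0, 600.0)
        assert windows.pre10 == (600.0, 1200.0)
        assert windows.event == (1200.0, 1800.0)
        assert set(subsets) == {"Pre20", "Pre10", "Event"}

    def test_insufficient_pre_onset_coverage_rejected(self, psh_episode):
        with pytest.raises(ValueError, match="does not cover"):
            pipe.segment_windows(psh_episode.to_beat_series(), onset=1000.0)

    def test_constant_rate_beat_counts(self):
        beats = constant_beats(0.5, 1800.0)  # 120 b/min
        _, subsets = pipe.segment_windows(beats, onset=1200.0)
        for sub in subsets.values():
            assert abs(sub.n_beats - 1200) <= 1

    def test_partition_is_exact(self, nopsh_episode):
        beats = nopsh_episode.to_beat_series()
        _, subsets = pipe.segment_windows(beats, onset=1200.0)
        in_span = beats.beat_times[
            (beats.beat_times >= 0.0) & (beats.beat_times < 1800.0)
        ]
        combined = np.concatenate([s.beat_times for s in subsets.values()])
        assert np.array_equal(np.sort(combined), np.sort(in_span))
        assert combined.size == np.unique(combined).size


class TestExtractFeatures:
    def test_nopsh_window_yields_finite_features(self, nopsh_episode):
        _, subsets = pipe.segment_windows(
            nopsh_episode.to_beat_series(), onset=1200.0
        )
        fv = pipe.extract_features("ep0", "noPSH", "Event", subsets["Event"])
        for col in pipe.FEATURE_COLUMNS:
            assert np.isfinite(getattr(fv, col)), col

    def test_constant_rr_window_degenerates_cleanly(self):
        beats = constant_beats(0.5, 700.0)  # 0.5 s is exact in binary
        with pytest.warns(UserWarning):
            fv = pipe.extract_features("ep0", "noPSH", "Event", beats)
        assert fv.sdnn == 0.0
        assert fv.ci_short == 0.0 and fv.ci_long == 0.0
        assert np.isnan(fv.ln_vlf) and np.isnan(fv.ln_hf)

    def test_cohort_row_count_is_three_per_episode(self):
        df = pipe.cohort_features(n_psh=2, n_nopsh=2, seed=4)
        assert len(df) == 4 * 3
        assert set(df["window"]) == {"Pre20", "Pre10", "Event"}
        counts = df.groupby("condition").size()
        assert counts["PSH"] == 6 and counts["noPSH"] == 6

    def test_cohort_features_deterministic(self):
        a = pipe.cohort_features(n_psh=2, n_nopsh=2, seed=6)
        b = pipe.cohort_features(n_psh=2, n_nopsh=2, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestCompareConditions:
    @staticmethod
    def _toy_features(rng, delta=0.0, n=10):
        rows = []
        for i in range(n):
            base = rng.normal(0, 1)
            for cond, shift in (("PSH", delta), ("noPSH", 0.0)):
                rows.append(
                    {
                        "episode_id": f"ep{i}_{cond}",
                        "window": "Event",
                        "condition": cond,
                        "x": base + shift + rng.normal(0, 0.3),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        df = self._toy_features(rng)
        vals = rng.normal(0, 1, 10)
        df.loc[df.condition == "PSH", "x"] = vals
        df.loc[df.condition == "noPSH", "x"] = vals  # identical groups
        gc = pipe.compare_conditions(df, "x", "independent", ("PSH", "noPSH"))
        assert np.isclose(gc.t_statistic, 0.0)
        assert np.isclose(gc.p_value, 1.0)
        assert np.isclose(gc.effect_r2, 0.0)

    def test_bonferroni_threshold_value(self):
        rng = np.random.default_rng(1)
        gc = pipe.compare_conditions(
            self._toy_features(rng), "x", "independent", ("PSH", "noPSH"),
            bonferroni_divisor=44,
        )
        assert round(gc.alpha_bonferroni, 3) == 0.001

    def test_independent_t_matches_oracle(self):
        rng = np.random.default_rng(2)
        df = self._toy_features(rng, delta=0.8)
        gc = pipe.compare_conditions(df, "x", "independent", ("PSH", "noPSH"))
        x = df[df.condition == "PSH"]["x"].to_numpy()
        y = df[df.condition == "noPSH"]["x"].to_numpy()
        t_ref, df_ref = t_statistic_independent(x, y)
        assert np.isclose(gc.t_statistic, t_ref, rtol=1e-9)
        assert gc.df == df_ref

    def test_paired_t_matches_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            base = rng.normal(0, 1)
            rows.append({"episode_id": f"ep{i}", "window": "Pre10",
                         "condition": "PSH", "x": base})
            rows.append({"episode_id": f"ep{i}", "window": "Event",
                         "condition": "PSH", "x": base - 0.5 + rng.normal(0, 0.2)})
        df = pd.DataFrame(rows)
        gc = pipe.compare_conditions(
            df, "x", "paired", ("Pre10", "Event"), group_col="window"
        )
        x = df[df.window == "Pre10"].set_index("episode_id")["x"]
        y = df[df.window == "Event"].set_index("episode_id")["x"]
        t_ref, df_ref = t_statistic_paired(x.to_numpy(), y.loc[x.index].to_numpy())
        assert np.isclose(gc.t_statistic, t_ref, rtol=1e-8)
        assert gc.df == df_ref

    def test_shapiro_matches_r_oracle(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(0, 1, 15), 6)
        from scipy import stats

        ours = stats.shapiro(x).pvalue  # the implementation's backend
        vec = ",".join(f"{v:.6f}" for v in x)
        out = subprocess.run(
            ["Rscript", "-e", f"cat(shapiro.test(c({vec}))$p.value)"],
            capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        assert np.isclose(ours, float(out.stdout.strip()), rtol=1e-6)

    def test_event_window_mean_hr_contrast_significant(
        self, small_cohort_features
    ):
        gc = pipe.compare_conditions(
            small_cohort_features, "mean_hr", "independent",
            ("PSH", "noPSH"), window="Event",
        )
        assert gc.t_statistic > 0  # PSH faster
        assert gc.p_value < 0.05  # full-power check runs at cohort scale

    def test_standard_battery_shape(self, small_cohort_features):
        table = pipe.standard_comparisons(small_cohort_features)
        # 10 measures x (3 independent + 4 paired) contrasts
        assert len(table) == len(pipe.FEATURE_COLUMNS) * 7
        assert (table["alpha_bonferroni"].round(5) == round(0.05 / 44, 5)).all()


class TestPSHAMScore:
    def test_all_zero_is_unlikely(self):
        score = pipe.psh_am_score([0] * 6, [0] * 11)
        assert score.combined == 0
        assert score.category == "unlikely"
        assert not score.severe_features

    def test_probable_band(self):
        score = pipe.psh_am_score([3, 3, 3, 2, 2, 2], [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert score.cfs_total == 15
        assert score.dlt_total == 6
        assert score.combined == 21
        assert score.category == "probable PSH"

    def test_severe_features_flag(self):
        score = pipe.psh_am_score([3, 3, 3, 3, 1, 1], [0] * 11)
        assert score.cfs_total == 14
        assert score.severe_features

    def test_item_validation(self):
        with pytest.raises(ValueError, match="CFS"):
            pipe.psh_am_score([4, 0, 0, 0, 0, 0], [0] * 11)
        with pytest.raises(ValueError, match="DLT"):
            pipe.psh_am_score([0] * 6, [2] + [0] * 10)
        with pytest.raises(ValueError):
            pipe.psh_am_score([0] * 5, [0] * 11)
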