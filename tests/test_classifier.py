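import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pshwatch import classifier as clf


def _toy_table(rng, n_per_class=24, sep=3.0, n_noise=3, informative="f0"):
    """Two-class table with one informative feature (sep SDs apart) plus
    pure-noise features."""
    rows = []
    for cond in ("PSH", "noPSH"):
        shift = sep if cond == "PSH" else 0.0
        for i in range(n_per_class):
            row = {
                "episode_id": f"{cond}_{i}",
                "condition": cond,
                informative: rng.normal(shift, 1.0),
            }
            for k in range(n_noise):
                row[f"noise{k}"] = rng.normal(0, 1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestComputeMetrics:
    def test_pre10_reference_matrix(self):
        m = clf.compute_metrics(clf.ConfusionMatrix(tp=16, fn=8, fp=0, tn=24))
        assert np.isclose(m.sensitivity, 2 / 3)
        assert m.specificity == 1.0
        assert np.isclose(m.balanced_accuracy, 5 / 6)
        assert np.isclose(m.f1, 0.8)

    def test_perfect_classification(self):
        m = clf.compute_metrics(clf.ConfusionMatrix(tp=24, fn=0, fp=0, tn=24))
        assert m.sensitivity == m.specificity == m.balanced_accuracy == m.f1 == 1.0
        assert m.misclassification_rate == 0.0

    def test_total_inversion(self):
        m = clf.compute_metrics(clf.ConfusionMatrix(tp=0, fn=24, fp=24, tn=0))
        assert m.sensitivity == 0.0 and m.specificity == 0.0
        assert m.balanced_accuracy == 0.0
        assert m.misclassification_rate == 1.0

    def test_no_predicted_positives_gives_missing_f1(self):
        m = clf.compute_metrics(clf.ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
        assert np.isnan(m.f1)

    def test_requires_both_actual_classes(self):
        with pytest.raises(ValueError):
            clf.compute_metrics(clf.ConfusionMatrix(tp=3, fn=2, fp=0, tn=0))

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(deadline=None, max_examples=200)
    def test_algebraic_identities(self, tp, fn, fp, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = clf.compute_metrics(clf.ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
        assert 0.0 <= m.sensitivity <= 1.0
        assert 0.0 <= m.specificity <= 1.0
        assert np.isclose(
            m.balanced_accuracy, (m.sensitivity + m.specificity) / 2
        )
        assert np.isclose(
            m.misclassification_rate, (fn + fp) / (tp + fn + fp + tn)
        )
        if tp + fp > 0 and tp > 0:
            precision = tp / (tp + fp)
            assert np.isclose(
                m.f1, 2 * precision * m.sensitivity / (precision + m.sensitivity)
            )


class TestSelectFeatures:
    def test_informative_feature_ranked_first(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            df = _toy_table(rng, sep=3.0)
            selected, imp = clf.select_features(
                df, feature_names=["f0", "noise0", "noise1", "noise2"], seed=seed
            )
            assert imp.index[0] == "f0"
            assert "f0" in selected

    def test_pure_noise_importance_stays_diffuse(self):
        maxima = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = _toy_table(rng, sep=0.0, n_noise=4)
            _, imp = clf.select_features(
                df, feature_names=["f0"] + [f"noise{k}" for k in range(4)],
                seed=seed,
            )
            maxima.append(imp.max())
        assert np.mean(maxima) < 2.0 / 5.0

    def test_constant_feature_gets_zero_importance(self):
        rng = np.random.default_rng(0)
        df = _toy_table(rng)
        df["flat"] = 1.0
        _, imp = clf.select_features(
            df, feature_names=["f0", "flat", "noise0"], seed=0
        )
        assert imp["flat"] == 0.0


class TestCrossvalidate:
    def test_separable_data_classified_perfectly(self):
        rng = np.random.default_rng(1)
        df = _toy_table(rng, sep=6.0)
        res = clf.crossvalidate(
            clf.ModelConfig(cost_c=2.0, gamma=0.5), df,
            feature_names=["f0", "noise0"], seed=1,
        )
        assert res["validation"].misclassification_rate == 0.0

    def test_constant_features_are_chance_level(self):
        rng = np.random.default_rng(2)
        df = _toy_table(rng)
        df["flat"] = 0.0
        res = clf.crossvalidate(
            clf.ModelConfig(cost_c=2.0, gamma=0.5), df,
            feature_names=["flat"], seed=2,
        )
        assert abs(res["validation"].balanced_accuracy - 0.5) <= 0.1

    def test_stratified_folds_on_48_samples(self):
        rng = np.random.default_rng(3)
        df = _toy_table(rng)
        from sklearn.model_selection import StratifiedKFold

        y = (df["condition"] == "PSH").to_numpy()
        X = df[["f0"]].to_numpy()
        for _, test_idx in StratifiedKFold(10, shuffle=True, random_state=0).split(X, y):
            assert 4 <= test_idx.size <= 5
            assert 0 < y[test_idx].sum() < test_idx.size

    def test_k_larger_than_class_count_rejected(self):
        rng = np.random.default_rng(4)
        df = _toy_table(rng, n_per_class=6)
        with pytest.raises(ValueError, match="leave-one-out"):
            clf.crossvalidate(clf.ModelConfig(1.0, 1.0), df,
                              feature_names=["f0"], k=10)

    def test_permuted_labels_are_chance_level(self):
        """Leakage canary: shuffling labels must collapse validation
        performance to chance (per-fold standardization leaks nothing)."""
        bas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = _toy_table(rng, sep=3.0)
            df["condition"] = rng.permutation(df["condition"].to_numpy())
            res = clf.crossvalidate(
                clf.ModelConfig(2.0, 0.5), df, feature_names=["f0", "noise0"],
                seed=seed,
            )
            bas.append(res["validation"].balanced_accuracy)
        assert 0.35 <= np.mean(bas) <= 0.65


class TestGridSearch:
    def test_grid_has_100_configs_in_stated_ranges(self):
        grid = clf.default_grid()
        assert len(grid) == 100
        assert all(0.5 <= c.cost_c <= 10.0 for c in grid)
        assert all(0.01 <= c.gamma <= 10.0 for c in grid)

    def test_well_separated_data_many_perfect_configs(self):
        rng = np.random.default_rng(5)
        df = _toy_table(rng, sep=5.0)
        result = clf.grid_search(df, feature_names=["f0", "noise0"], seed=5)
        perfect = sum(
            1 for _, _, val in result.evaluated
            if val.misclassification_rate == 0.0
        )
        assert perfect >= 45

    def test_duplicated_column_equivalent_on_separable_data(self):
        rng = np.random.default_rng(6)
        df = _toy_table(rng, sep=4.0)
        df["f0_copy"] = df["f0"]
        single = clf.crossvalidate(clf.ModelConfig(2.0, 0.5), df,
                                   feature_names=["f0"], seed=6)
        double = clf.crossvalidate(clf.ModelConfig(2.0, 0.5), df,
                                   feature_names=["f0", "f0_copy"], seed=6)
        assert vars(single["validation_cm"]) == vars(double["validation_cm"])

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        df = _toy_table(rng, sep=2.0)
        a = clf.grid_search(df, feature_names=["f0", "noise0"], seed=7)
        b = clf.grid_search(df, feature_names=["f0", "noise0"], seed=7)
        assert vars(a.best) == vars(b.best)
        for (_, _, va), (_, _, vb) in zip(a.evaluated, b.evaluated):
            assert vars(va) == vars(vb)

    def test_tie_break_prefers_smaller_c_then_gamma(self):
        rng = np.random.default_rng(8)
        df = _toy_table(rng, sep=5.0)  # many ties at perfect accuracy
        result = clf.grid_search(df, feature_names=["f0"], seed=8)
        perfect = [
            cfg for cfg, _, val in result.evaluated
            if val.balanced_accuracy == 1.0
        ]
        assert result.best.cost_c == min(c.cost_c for c in perfect)


class TestFeatureAblation:
    def test_removing_sole_informative_feature_collapses(self):
        rng = np.random.default_rng(9)
        df = _toy_table(rng, sep=4.0)
        table = clf.feature_ablation(
            clf.ModelConfig(2.0, 0.5), df,
            feature_names=["f0", "noise0", "noise1"], seed=9,
        )
        assert abs(table.loc["f0", "balanced_accuracy"] - 0.5) <= 0.15
        for noise in ("noise0", "noise1"):
            assert abs(table.loc[noise, "balanced_accuracy_drop"]) < 0.05

    def test_redundant_copy_removal_changes_nothing(self):
        rng = np.random.default_rng(10)
        df = _toy_table(rng, sep=4.0)
        df["f0_copy"] = df["f0"]
        table = clf.feature_ablation(
            clf.ModelConfig(2.0, 0.5), df,
            feature_names=["f0", "f0_copy"], seed=10,
        )
        assert table.loc["f0_copy", "balanced_accuracy_drop"] == 0.0
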