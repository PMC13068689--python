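"""RBF-kernel maximum-margin classification of PSH vs noPSH windows.

Random-forest impurity importance ranks the HRV features; an RBF support
vector machine is tuned over a 10x10 log-spaced grid (C in [0.5, 10],
gamma in [0.01, 10], 100 configurations) by stratified tenfold
cross-validation, with per-fold standardization fitted on training folds
only.  Validation metrics pool the out-of-fold confusion matrix
(fold-averaged metrics available by flag); a leave-one-feature-out
ablation quantifies each feature's contribution.  PSH is the positive
class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SVM_FEATURES",
    "ModelConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "SearchResult",
    "select_features",
    "grid_search",
    "crossvalidate",
    "compute_metrics",
    "feature_ablation",
]

#: The candidate HRV predictors (heart rate itself is deliberately absent:
#: the model should anticipate the storm, not restate the tachycardia).
SVM_FEATURES = [
    "sdnn",
    "ln_vlf",
    "ln_lf",
    "ln_hf",
    "lf_hf_ratio",
    "ci_short",
    "ci_long",
]

POSITIVE_LABEL = "PSH"


@dataclass
class ModelConfig:
    cost_c: float
    gamma: float
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.cost_c <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    f1: float
    misclassification_rate: float


@dataclass
class SearchResult:
    evaluated: list  # (ModelConfig, train ClassMetrics, validation ClassMetrics)
    best: ModelConfig
    n_models: int


def compute_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, specificity, balanced accuracy, F1, misclassification.

    Requires at least one actual positive and one actual negative; F1 is
    NaN when precision is undefined (no predicted positives).
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("need at least one sample of each actual class")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
        f1 = (
            2 * precision * sens / (precision + sens)
            if precision + sens > 0
            else 0.0
        )
    else:
        f1 = float("nan")
    return ClassMetrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        f1=f1,
        misclassification_rate=(cm.fn + cm.fp) / cm.total,
    )


def _as_xy(
    features: pd.DataFrame, feature_names: list[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = feature_names or [c for c in SVM_FEATURES if c in features.columns]
    X = features[names].to_numpy(dtype=float)
    y = (features["condition"] == POSITIVE_LABEL).to_numpy()
    keep = np.isfinite(X).all(axis=1)
    return X[keep], y[keep], names


def select_features(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    n_trees: int = 500,
    cumulative: float = 0.80,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Rank features by random-forest impurity importance.

    Returns the top-ranked subset covering ``cumulative`` total importance
    and the full ranked importance series.  Constant features get zero
    importance, never an error.
    """
    X, y, names = _as_xy(features, feature_names)
    if len(names) < 2 or X.shape[0] < 10:
        raise ValueError("need >= 2 features and >= 10 rows")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    imp = pd.Series(forest.feature_importances_, index=names).sort_values(
        ascending=False
    )
    cum = imp.cumsum()
    k = int(np.searchsorted(cum.to_numpy(), cumulative) + 1)
    return imp.index[: min(k, len(imp))].tolist(), imp


def _fold_matrices(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int,
) -> tuple[list[ConfusionMatrix], list[ConfusionMatrix]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    train_cms, val_cms = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = make_pipeline(
            StandardScaler(), SVC(C=config.cost_c, gamma=config.gamma, kernel="rbf")
        )
        model.fit(X[train_idx], y[train_idx])
        for idx, sink in ((train_idx, train_cms), (test_idx, val_cms)):
            pred = model.predict(X[idx])
            truth = y[idx]
            sink.append(
                ConfusionMatrix(
                    tp=int(np.sum(pred & truth)),
                    fn=int(np.sum(~pred & truth)),
                    fp=int(np.sum(pred & ~truth)),
                    tn=int(np.sum(~pred & ~truth)),
                )
            )
    return train_cms, val_cms


def _pool(cms: list[ConfusionMatrix]) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=sum(c.tp for c in cms),
        fn=sum(c.fn for c in cms),
        fp=sum(c.fp for c in cms),
        tn=sum(c.tn for c in cms),
    )


def crossvalidate(
    config: ModelConfig,
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    pooled: bool = True,
) -> dict:
    """Stratified k-fold cross-validation of one SVM configuration.

    Standardization is fitted inside each training fold (no leakage).
    Returns pooled train/validation confusion matrices and metrics; with
    ``pooled=False`` metrics are averaged over folds instead.
    """
    X, y, names = _as_xy(features, feature_names)
    smallest = min(int(y.sum()), int((~y).sum()))
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({smallest}); "
            "consider leave-one-out"
        )
    train_cms, val_cms = _fold_matrices(config, X, y, k, seed)
    train_cm, val_cm = _pool(train_cms), _pool(val_cms)
    if pooled:
        train_metrics = compute_metrics(train_cm)
        val_metrics = compute_metrics(val_cm)
    else:
        def _avg(cms):
            ms = [compute_metrics(c) for c in cms if c.tp + c.fn and c.tn + c.fp]
            return ClassMetrics(
                **{
                    f: float(np.nanmean([getattr(m, f) for m in ms]))
                    for f in vars(ms[0])
                }
            )
        train_metrics, val_metrics = _avg(train_cms), _avg(val_cms)
    return {
        "config": config,
        "features": names,
        "train_cm": train_cm,
        "validation_cm": val_cm,
        "train": train_metrics,
        "validation": val_metrics,
    }


def default_grid(n_c: int = 10, n_gamma: int = 10) -> list[ModelConfig]:
    """Log-spaced C in [0.5, 10] x gamma in [0.01, 10] (100 configs)."""
    return [
        ModelConfig(cost_c=float(c), gamma=float(g))
        for c in np.geomspace(0.5, 10.0, n_c)
        for g in np.geomspace(0.01, 10.0, n_gamma)
    ]


def random_grid(n: int = 100, seed: int = 0) -> list[ModelConfig]:
    """Seeded log-uniform random search over the same ranges."""
    rng = np.random.default_rng(seed)
    cs = np.exp(rng.uniform(np.log(0.5), np.log(10.0), n))
    gs = np.exp(rng.uniform(np.log(0.01), np.log(10.0), n))
    return [ModelConfig(cost_c=float(c), gamma=float(g)) for c, g in zip(cs, gs)]


def grid_search(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    grid: list[ModelConfig] | None = None,
    k: int = 10,
    seed: int = 0,
) -> SearchResult:
    """Evaluate every configuration by tenfold stratified CV.

    The best configuration maximizes validation balanced accuracy; ties
    break toward smaller C, then smaller gamma.  Deterministic for a fixed
    fold seed.
    """
    grid = grid or default_grid()
    evaluated = []
    for config in grid:
        res = crossvalidate(config, features, feature_names, k=k, seed=seed)
        evaluated.append((config, res["train"], res["validation"]))
    best = max(
        evaluated,
        key=lambda e: (e[2].balanced_accuracy, -e[0].cost_c, -e[0].gamma),
    )[0]
    return SearchResult(evaluated=evaluated, best=best, n_models=len(grid))


def feature_ablation(
    config: ModelConfig,
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-feature-out cross-validation.

    One row per ablated feature (plus the 'none' baseline) with validation
    metrics, the balanced-accuracy drop, and per-class misclassification
    (overall / PSH / noPSH - the three-bar summary).
    """
    _, _, names = _as_xy(features, feature_names)
    if len(names) < 2:
        raise ValueError("ablation needs >= 2 features")
    rows = []

    def _row(label: str, used: list[str]):
        res = crossvalidate(config, features, used, k=k, seed=seed)
        cm = res["validation_cm"]
        m = res["validation"]
        rows.append(
            {
                "ablated": label,
                "balanced_accuracy": m.balanced_accuracy,
                "misclassification_rate": m.misclassification_rate,
                "miscls_psh": cm.fn / (cm.tp + cm.fn),
                "miscls_nopsh": cm.fp / (cm.fp + cm.tn),
                "train_misclassification_rate": res["train"].misclassification_rate,
            }
        )

    _row("none", names)
    for feat in names:
        _row(feat, [f for f in names if f != feat])
    df = pd.DataFrame(rows).set_index("ablated")
    df["balanced_accuracy_drop"] = (
        df.loc["none", "balanced_accuracy"] - df["balanced_accuracy"]
    )
    return df
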