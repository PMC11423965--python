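"""Random-forest temperature regression with Gini-importance feature selection.

Workflow: z-score the 104 features with training-split statistics, rank them
by impurity-decrease (variance-reduction) importance from a regression
forest, keep the top 10, then fit the final forest on those, choosing
hyperparameters from a small grid by validation MAE.  Models are trained per
power group (15 W and 20 W heat differently, so their informative textures
differ).

sklearn's ``feature_importances_`` are normalized to sum to 1; only the
ranking is meaningful across implementations, not the magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import stats as _scipy_stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .features import FEATURE_NAMES, NormalizationStats, apply_normalizer

VALIDATION_GRID = ((200, 1), (200, 5), (500, 1), (500, 5))  # (n_trees, min_leaf)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: float = 1.0 / 3.0
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")


@dataclass(frozen=True)
class ImportanceRanking:
    """Feature names with Gini importances, in non-increasing order."""

    entries: tuple[tuple[str, float], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)


@dataclass
class TrainedTemperatureModel:
    selected_features: tuple[str, ...]
    stats: NormalizationStats
    forest: RandomForestRegressor
    power_group: str
    config: ForestConfig
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedTemperatureModel":
        return joblib.load(path)


def _forest(cfg: ForestConfig, n_trees=None, min_leaf=None) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees or cfg.n_trees,
        max_features=cfg.max_features,
        min_samples_leaf=min_leaf or cfg.min_leaf,
        random_state=cfg.seed,
        n_jobs=1,
    )


def rank_importance(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ForestConfig,
    feature_names=FEATURE_NAMES,
) -> ImportanceRanking:
    """Rank features by regression-forest impurity-decrease importance.

    Ties (including the all-zero importances of a constant target) break by
    canonical feature order, so the ranking is always deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(X) < 50:
        raise ValueError("need at least 50 training samples to rank features")
    if np.ptp(y) == 0:
        warnings.warn("constant target: all importances are zero", stacklevel=2)
        imp = np.zeros(X.shape[1])
    else:
        imp = _forest(cfg).fit(X, y).feature_importances_
    order = np.argsort(-imp, kind="stable")  # stable => canonical-order ties
    return ImportanceRanking(
        entries=tuple((feature_names[i], float(imp[i])) for i in order)
    )


def select_top_k(ranking: ImportanceRanking, k: int = 10) -> tuple[str, ...]:
    if k > len(ranking.entries):
        raise ValueError("k exceeds ranking length")
    return ranking.names[:k]


def fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ForestConfig,
    selected_features: tuple[str, ...],
    stats: NormalizationStats,
    power_group: str = "P15",
) -> TrainedTemperatureModel:
    """Fit the final forest on the selected (already normalized) features.

    A small grid (n_trees in {200, 500} x min_leaf in {1, 5}) is scored on
    the validation split by MAE and the best is kept.
    """
    best = None
    for n_trees, min_leaf in VALIDATION_GRID:
        forest = _forest(cfg, n_trees=n_trees, min_leaf=min_leaf).fit(X_train, y_train)
        val_mae = mae(y_val, forest.predict(X_val))
        if best is None or val_mae < best[0]:
            best = (val_mae, forest, n_trees, min_leaf)
    val_mae, forest, n_trees, min_leaf = best
    return TrainedTemperatureModel(
        selected_features=tuple(selected_features),
        stats=stats,
        forest=forest,
        power_group=power_group,
        config=cfg,
        metadata={
            "val_mae_C": val_mae,
            "n_trees": n_trees,
            "min_leaf": min_leaf,
            "seed": cfg.seed,
            "n_train": len(X_train),
        },
    )


def predict(model: TrainedTemperatureModel, X_full: np.ndarray) -> np.ndarray:
    """Predict temperatures from raw (unnormalized) 104-feature vectors."""
    X_full = np.atleast_2d(np.asarray(X_full, dtype=np.float64))
    if X_full.shape[1] != len(model.stats.feature_names):
        raise ValueError("feature vector length does not match the model")
    Xn = apply_normalizer(model.stats, X_full)
    idx = [model.stats.feature_names.index(n) for n in model.selected_features]
    return model.forest.predict(Xn[:, idx])


def train_temperature_model(
    X: np.ndarray,
    y: np.ndarray,
    split_labels,
    cfg: ForestConfig,
    power_group: str = "P15",
    k: int = 10,
    feature_names=FEATURE_NAMES,
) -> TrainedTemperatureModel:
    """The whole training pipeline on a pre-split feature table."""
    from .features import fit_normalizer

    labels = np.asarray(split_labels)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    tr, va = labels == "train", labels == "val"
    stats = fit_normalizer(X[tr], feature_names)
    Xn = apply_normalizer(stats, X)
    ranking = rank_importance(Xn[tr], y[tr], cfg, feature_names=feature_names)
    selected = select_top_k(ranking, k=k)
    idx = [feature_names.index(n) for n in selected]
    model = fit(
        Xn[tr][:, idx], y[tr], Xn[va][:, idx], y[va], cfg, selected, stats,
        power_group=power_group,
    )
    model.metadata["ranking"] = ranking.entries[: max(k, 20)]
    return model


@dataclass(frozen=True)
class PredictionMetrics:
    """Point-prediction accuracy summary; rmse >= mae always holds."""

    mae_C: float
    rmse_C: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse_C < self.mae_C - 1e-12:
            raise ValueError("rmse cannot be below mae")


def evaluate_predictions(y: np.ndarray, y_hat: np.ndarray) -> PredictionMetrics:
    """MAE/RMSE of predicted vs thermocouple temperatures."""
    return PredictionMetrics(mae_C=mae(y, y_hat), rmse_C=rmse(y, y_hat), n=len(np.asarray(y)))


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute error, (1/n) * sum |y_i - yhat_i|."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(mean_absolute_error(y, y_hat))


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(mean_squared_error(y, y_hat)))


def feature_temperature_correlation(feature: np.ndarray, temperature: np.ndarray) -> float:
    """Pearson correlation between one feature series and temperature.

    Returns NaN for constant series (the correlation is undefined there).
    """
    feature = np.asarray(feature, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if feature.size < 3 or feature.size != temperature.size:
        raise ValueError("need two equal series of length >= 3")
    if np.ptp(feature) == 0 or np.ptp(temperature) == 0:
        return float("nan")
    return float(_scipy_stats.pearsonr(feature, temperature)[0])
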