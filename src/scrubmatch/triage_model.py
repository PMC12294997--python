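"""Triage-acuity regression from vital signs.

Acuity (ESI scale, 1 = most urgent .. 5 = least) is treated as a regression
target predicted from seven vitals: temperature (deg F), heart rate (bpm),
respiratory rate (breaths/min), oxygen saturation (%), systolic and
diastolic blood pressure (mmHg) and self-reported pain (0-10).  Candidate
models span nine standard regressors, from linear baselines to
histogram-based gradient boosting; model selection runs shuffled k-fold
cross-validation (default k = 5) and picks the lowest mean absolute error.

MAE, MSE and R^2 are computed directly from their definitions:

    MAE = mean(|y - yhat|)
    MSE = mean((y - yhat)^2)
    R^2 = 1 - RSS / TSS,  TSS about the mean of y

with constant-truth R^2 reported as NaN (TSS = 0) rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold

__all__ = [
    "FEATURE_ORDER",
    "SUPPORTED_MODELS",
    "VitalsRecord",
    "ModelConfig",
    "RegressionReport",
    "TriageModel",
    "ModelError",
    "FoldError",
    "build_estimator",
    "kfold_indices",
    "train_acuity_model",
    "predict_acuity",
    "acuity_to_level",
    "regression_metrics",
    "cross_validate",
    "select_best_model",
]

#: Fixed feature ordering for every model fit and predict call.
FEATURE_ORDER: tuple[str, ...] = (
    "temperature",
    "heartrate",
    "resprate",
    "o2sat",
    "sbp",
    "dbp",
    "pain",
)

_MODEL_CLASSES = {
    "LinearRegression": LinearRegression,
    "Ridge": Ridge,
    "Lasso": Lasso,
    "RandomForest": RandomForestRegressor,
    "GradientBoosting": GradientBoostingRegressor,
    "AdaBoost": AdaBoostRegressor,
    "Bagging": BaggingRegressor,
    "ExtraTrees": ExtraTreesRegressor,
    "HistGradientBoosting": HistGradientBoostingRegressor,
}

SUPPORTED_MODELS: tuple[str, ...] = tuple(sorted(_MODEL_CLASSES))

_SEEDED_MODELS = frozenset(
    {"RandomForest", "GradientBoosting", "AdaBoost", "Bagging", "ExtraTrees", "HistGradientBoosting"}
)


class ModelError(ValueError):
    """Raised for unknown model names or predicting with an untrained model."""


class FoldError(ValueError):
    """Raised when the fold count is incompatible with the data size."""


@dataclass(frozen=True)
class VitalsRecord:
    """One triage-table row; ``acuity`` is optional at predict time."""

    temperature: float
    heartrate: float
    resprate: float
    o2sat: float
    sbp: float
    dbp: float
    pain: int
    acuity: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.o2sat <= 100:
            raise ValueError(f"o2sat must be in [0, 100], got {self.o2sat}")
        if not 0 <= self.pain <= 10:
            raise ValueError(f"pain must be in [0, 10], got {self.pain}")
        if self.acuity is not None and not 1 <= self.acuity <= 5:
            raise ValueError(f"acuity must be in 1..5, got {self.acuity}")

    def features(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in FEATURE_ORDER)


@dataclass(frozen=True)
class ModelConfig:
    """A named regressor plus hyperparameter overrides.

    Unlisted hyperparameters keep the library defaults; the effective
    parameters are recorded in the fitted model for provenance.
    """

    model_name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_name not in _MODEL_CLASSES:
            raise ModelError(
                f"unknown model {self.model_name!r}; supported: {', '.join(SUPPORTED_MODELS)}"
            )
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


@dataclass(frozen=True)
class RegressionReport:
    """Per-fold and aggregate cross-validation metrics for one config."""

    config: ModelConfig
    k: int
    seed: int
    fold_mae: tuple[float, ...]
    fold_mse: tuple[float, ...]
    fold_r2: tuple[float, ...]

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    def standard_errors(self) -> dict[str, float]:
        out = {}
        for name, folds in (("mae", self.fold_mae), ("mse", self.fold_mse), ("r2", self.fold_r2)):
            arr = np.asarray(folds, dtype=float)
            out[name] = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        return out

    def summary(self) -> dict:
        se = self.standard_errors()
        return {
            "model": self.config.model_name,
            "hyperparameters": dict(self.config.hyperparameters),
            "k": self.k,
            "seed": self.seed,
            "mae_mean": self.mean_mae,
            "mae_se": se["mae"],
            "mse_mean": self.mean_mse,
            "mse_se": se["mse"],
            "r2_mean": self.mean_r2,
            "r2_se": se["r2"],
        }


@dataclass
class TriageModel:
    """A fitted regressor bundled with its provenance manifest."""

    config: ModelConfig
    seed: int
    estimator: object = None
    feature_order: tuple[str, ...] = FEATURE_ORDER

    @property
    def fitted(self) -> bool:
        return self.estimator is not None and hasattr(self.estimator, "predict")


def build_estimator(config: ModelConfig, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a config."""
    params = dict(config.hyperparameters)
    if config.model_name in _SEEDED_MODELS:
        params.setdefault("random_state", seed)
    return _MODEL_CLASSES[config.model_name](**params)


def _as_feature_frame(vitals) -> pd.DataFrame:
    if isinstance(vitals, pd.DataFrame):
        missing = [c for c in FEATURE_ORDER if c not in vitals.columns]
        if missing:
            raise ValueError(f"vitals table missing columns {missing}")
        return vitals.loc[:, list(FEATURE_ORDER)]
    rows = [v.features() for v in vitals]
    return pd.DataFrame(rows, columns=list(FEATURE_ORDER))


def train_acuity_model(dataset: pd.DataFrame, config: ModelConfig, seed: int = 0) -> TriageModel:
    """Fit one regressor on a labeled vitals table (needs an acuity column)."""
    if "acuity" not in dataset.columns:
        raise ValueError("training data must contain an 'acuity' column")
    X = _as_feature_frame(dataset).to_numpy(dtype=float)
    y = dataset["acuity"].to_numpy(dtype=float)
    est = build_estimator(config, seed)
    est.fit(X, y)
    return TriageModel(config=config, seed=seed, estimator=est)


def predict_acuity(model: TriageModel, vitals) -> np.ndarray:
    """Predict real-valued acuity for records or a vitals table."""
    if not model.fitted:
        raise ModelError("model has not been trained")
    X = _as_feature_frame(vitals).to_numpy(dtype=float)
    yhat = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(yhat)):
        raise ModelError("model produced non-finite predictions")
    return yhat


def acuity_to_level(yhat) -> np.ndarray:
    """Round half away from zero, then clip to the 1..5 ESI scale."""
    arr = np.asarray(yhat, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("predictions must be finite")
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return np.clip(rounded, 1, 5).astype(int)


def regression_metrics(y, yhat) -> tuple[float, float, float]:
    """(MAE, MSE, R^2) straight from the definitions.

    R^2 uses TSS about the mean of ``y``; constant truth makes TSS zero and
    R^2 undefined, reported as NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError(f"y and yhat must be equal-length nonempty vectors, got {y.shape} vs {yhat.shape}")
    resid = y - yhat
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("constant truth vector: R^2 is undefined (TSS = 0)", RuntimeWarning)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / tss
    return mae, mse, r2


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold split of range(n): disjoint, exhaustive test folds."""
    if k < 2:
        raise FoldError(f"k must be >= 2, got {k}")
    if k > n:
        raise FoldError(f"cannot split {n} records into {k} folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.arange(n)))


def cross_validate(
    dataset: pd.DataFrame,
    configs: Sequence[ModelConfig],
    k: int = 5,
    seed: int = 0,
) -> list[RegressionReport]:
    """Shuffled k-fold cross-validation of every config on one dataset.

    Folds are identical across configs (same shuffle seed), so reports are
    directly comparable.  Metrics are reported in absolute value: lower MAE
    and MSE are better, higher R^2 is better.
    """
    folds = kfold_indices(len(dataset), k, seed)
    X = _as_feature_frame(dataset).to_numpy(dtype=float)
    if "acuity" not in dataset.columns:
        raise ValueError("cross-validation requires an 'acuity' column")
    y = dataset["acuity"].to_numpy(dtype=float)
    reports = []
    for config in configs:
        maes, mses, r2s = [], [], []
        for train_idx, test_idx in folds:
            est = build_estimator(config, seed)
            est.fit(X[train_idx], y[train_idx])
            yhat = est.predict(X[test_idx])
            mae, mse, r2 = regression_metrics(y[test_idx], yhat)
            maes.append(mae)
            mses.append(mse)
            r2s.append(r2)
        reports.append(
            RegressionReport(
                config=config, k=k, seed=seed,
                fold_mae=tuple(maes), fold_mse=tuple(mses), fold_r2=tuple(r2s),
            )
        )
    return reports


def select_best_model(reports: Sequence[RegressionReport]) -> ModelConfig:
    """Lowest mean MAE wins; ties fall to MSE, then R^2, then name order."""
    if not reports:
        raise ValueError("no reports to select from")
    best = min(
        reports,
        key=lambda rep: (rep.mean_mae, rep.mean_mse, -rep.mean_r2, rep.config.model_name),
    )
    return best.config
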