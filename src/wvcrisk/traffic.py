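"""Hazard submodels: random-forest regressions for traffic volume and speed.

Traffic volume (AADT, vehicles/day) is approximately log-normal, so the
forest is fitted to ln(AADT) and predictions are exponentiated back to
vehicles/day.  Posted speed (km/h) is modelled on the identity scale
from road class and road density only.  Both forests use 500 trees and
report out-of-bag percent variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .occurrence import correlation_prune

__all__ = [
    "TrafficModelFit",
    "VOLUME_PREDICTORS",
    "SPEED_PREDICTORS",
    "fit_volume_model",
    "fit_speed_model",
    "predict_traffic",
]

VOLUME_PREDICTORS = ["KMTODEV", "KMTOHWY", "POPDENS", "RDCLASS", "RDDENS"]
SPEED_PREDICTORS = ["RDCLASS", "RDDENS"]


@dataclass
class TrafficModelFit:
    """A fitted traffic forest plus its evaluation metrics.

    ``pct_variance_explained`` is computed from out-of-bag residuals:
    100 x (1 - MSE_oob / var(response)); ``importance`` re-scales the
    forest's impurity importances to percent.
    """

    model: RandomForestRegressor = field(repr=False)
    predictors: list[str]
    response_transform: str  # "log" for volume, "identity" for speed
    n_trees: int
    pct_variance_explained: float
    importance: pd.Series
    dropped_predictors: list[str]

    def predict(self, segments: pd.DataFrame) -> np.ndarray:
        return predict_traffic(self, segments)


def _fit_forest(
    X: pd.DataFrame, y: np.ndarray, transform: str, seed: int, n_trees: int, dropped: list[str]
) -> TrafficModelFit:
    model = RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(dtype=float), y)
    oob = model.oob_prediction_
    ok = np.isfinite(oob)
    pct = 100.0 * (1.0 - np.mean((y[ok] - oob[ok]) ** 2) / np.var(y[ok]))
    importance = pd.Series(model.feature_importances_, index=list(X.columns))
    importance = 100.0 * importance / importance.sum()
    return TrafficModelFit(
        model=model,
        predictors=list(X.columns),
        response_transform=transform,
        n_trees=n_trees,
        pct_variance_explained=float(pct),
        importance=importance,
        dropped_predictors=dropped,
    )


def fit_volume_model(
    train: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    predictors: list[str] | None = None,
    prune_threshold: float = 0.7,
    response_col: str = "AADT",
) -> TrafficModelFit:
    """Random forest for ln(AADT) from demographic/network predictors.

    Predictors are first screened so that all pairwise |r| stay below
    ``prune_threshold`` (default 0.7).  The response must be strictly
    positive; the fit is on its natural log.
    """
    y_raw = train[response_col].to_numpy(dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError("AADT must be strictly positive (log response)")
    cols = predictors or [c for c in VOLUME_PREDICTORS if c in train.columns]
    X, dropped = correlation_prune(train[cols], threshold=prune_threshold)
    return _fit_forest(X, np.log(y_raw), "log", seed, n_trees, dropped)


def fit_speed_model(
    train: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    predictors: list[str] | None = None,
    response_col: str = "SPEEDLMT",
) -> TrafficModelFit:
    """Random forest for posted speed from road class and road density."""
    y = train[response_col].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("speed limits must be strictly positive")
    cols = predictors or SPEED_PREDICTORS
    return _fit_forest(train[cols], y, "identity", seed, n_trees, [])


def predict_traffic(fit: TrafficModelFit, segments: pd.DataFrame) -> np.ndarray:
    """Per-segment volume (vehicles/day) or speed (km/h) predictions.

    Volume predictions are exponentiated back from the log scale and are
    therefore strictly positive.
    """
    missing = [c for c in fit.predictors if c not in segments.columns]
    if missing:
        raise KeyError(f"segments are missing predictor field(s): {missing}")
    pred = fit.model.predict(segments[fit.predictors].to_numpy(dtype=float))
    if fit.response_transform == "log":
        return np.exp(pred)
    return pred
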