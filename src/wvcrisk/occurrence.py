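"""Exposure submodel: boosted-tree species occurrence from presence/background data.

The submodel contrasts presence records with uniformly sampled
background (pseudo-absence) points using stochastic gradient-boosted
classification trees.  Tree complexity (terminal-node limit) 5 and
learning rate 0.005 are the defaults; the number of trees is chosen by
k-fold cross-validated deviance minimisation, the standard stagewise
early-stopping rule for boosted regression trees in distribution
modelling.  Predicting the fitted model over the covariate rasters
yields the relative-likelihood-of-occurrence layer that the collision
model samples at segment midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.inspection import partial_dependence
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .raster import CovariateRaster

__all__ = ["OccurrenceModelFit", "correlation_prune", "fit_occurrence", "predict_occurrence_raster"]

PREDICTION_FLOOR = 1e-6


@dataclass
class OccurrenceModelFit:
    """A fitted occurrence ensemble and its evaluation metrics."""

    model: GradientBoostingClassifier = field(repr=False)
    feature_names: list[str]
    n_trees: int
    tree_complexity: int
    learning_rate: float
    deviance_explained: float  # percent, on training data
    cv_deviance_mean: float
    cv_deviance_sd: float
    cv_auc_mean: float
    cv_auc_sd: float
    contributions: pd.Series  # per-variable percent, sums to 100
    partial_dependence: dict[str, tuple[np.ndarray, np.ndarray]]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of presence for a covariate table."""
        return self.model.predict_proba(X[self.feature_names].to_numpy(dtype=float))[:, 1]


def correlation_prune(
    table: pd.DataFrame, threshold: float = 0.75
) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop covariates until all pairwise |Pearson r| < threshold.

    At each step the pair with the largest |r| at or above the threshold
    is considered and the member with the larger mean absolute
    correlation to all remaining covariates is dropped (ties broken by
    column order, keeping the earlier column).  Constant columns have
    undefined correlations and are dropped first with a warning.

    Returns the reduced table and the list of dropped column names.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    dropped: list[str] = []
    work = table.copy()
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant column(s) with undefined correlation: {constant}",
            stacklevel=2,
        )
        work = work.drop(columns=constant)
        dropped.extend(constant)

    while work.shape[1] > 1:
        corr = work.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            break
        if i > j:  # deterministic pair orientation
            i, j = j, i
        mean_i = corr[i].sum() / (work.shape[1] - 1)
        mean_j = corr[j].sum() / (work.shape[1] - 1)
        victim = work.columns[j] if mean_j >= mean_i else work.columns[i]
        work = work.drop(columns=[victim])
        dropped.append(victim)
    return work, dropped


def _mean_binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    # float32 inputs would round 1 - 1e-12 back to 1.0; promote first
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit_occurrence(
    train: pd.DataFrame,
    tree_complexity: int = 5,
    learning_rate: float = 0.005,
    bag_fraction: float = 0.5,
    max_trees: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> OccurrenceModelFit:
    """Fit the boosted-tree occurrence submodel.

    Parameters
    ----------
    train : DataFrame
        One row per point; binary ``label`` column (1 presence, 0
        background) plus numeric covariates.
    tree_complexity : int
        Terminal-node limit per tree (allows interactions up to that
        order).
    learning_rate : float
        Per-tree shrinkage.
    bag_fraction : float
        Stochastic subsampling rate per boosting step.
    max_trees, cv_folds : int
        The ensemble size is the stage minimising mean k-fold
        cross-validated deviance, searched up to ``max_trees``.

    Notes
    -----
    ``deviance_explained`` is 100 x (null - residual)/null using mean
    binomial deviance on the training data; ``cv_auc`` is estimated on
    held-out folds only.
    """
    y = train[label_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both presence and background labels are required to fit")
    feature_names = [c for c in train.columns if c != label_col]
    X = train[feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariate table contains missing values; drop null rows first")

    def make_model(n_estimators: int, rs: int) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            max_leaf_nodes=tree_complexity,
            subsample=bag_fraction,
            random_state=rs,
        )

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_dev = np.empty((cv_folds, max_trees))
    fold_probs: list[tuple[np.ndarray, np.ndarray]] = []  # (y_test, staged prob matrix)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        model = make_model(max_trees, seed + k)
        model.fit(X[tr], y[tr])
        staged = np.empty((max_trees, len(te)), dtype=np.float32)
        for s, proba in enumerate(model.staged_predict_proba(X[te])):
            staged[s] = proba[:, 1]
        fold_dev[k] = [_mean_binomial_deviance(y[te], staged[s]) for s in range(max_trees)]
        fold_probs.append((y[te], staged))

    mean_dev = fold_dev.mean(axis=0)
    n_trees = int(np.argmin(mean_dev)) + 1
    cv_dev = fold_dev[:, n_trees - 1]
    cv_auc = np.array(
        [roc_auc_score(y_te, staged[n_trees - 1]) for y_te, staged in fold_probs]
    )

    final = make_model(n_trees, seed)
    final.fit(X, y)
    p_train = final.predict_proba(X)[:, 1]
    null_dev = _mean_binomial_deviance(y, np.full_like(y, y.mean()))
    resid_dev = _mean_binomial_deviance(y, p_train)
    dev_expl = 100.0 * (null_dev - resid_dev) / null_dev

    contrib = pd.Series(final.feature_importances_, index=feature_names)
    contrib = 100.0 * contrib / contrib.sum()

    pdp: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for idx, name in enumerate(feature_names):
        res = partial_dependence(final, X, features=[idx], grid_resolution=25, kind="average")
        pdp[name] = (np.asarray(res["grid_values"][0]), np.asarray(res["average"][0]))

    return OccurrenceModelFit(
        model=final,
        feature_names=feature_names,
        n_trees=n_trees,
        tree_complexity=tree_complexity,
        learning_rate=learning_rate,
        deviance_explained=dev_expl,
        cv_deviance_mean=float(cv_dev.mean()),
        cv_deviance_sd=float(cv_dev.std(ddof=1)),
        cv_auc_mean=float(cv_auc.mean()),
        cv_auc_sd=float(cv_auc.std(ddof=1)),
        contributions=contrib,
        partial_dependence=pdp,
    )


def predict_occurrence_raster(
    fit: OccurrenceModelFit, rasters: dict[str, CovariateRaster]
) -> CovariateRaster:
    """Predict the relative-likelihood-of-occurrence layer cell by cell.

    Requires one raster per training covariate, all on the same grid.
    No-data cells propagate to NaN; everywhere else the prediction is a
    probability clamped to [1e-6, 1 - 1e-9] so downstream logs are safe.
    """
    missing = [n for n in fit.feature_names if n not in rasters]
    if missing:
        raise KeyError(f"missing covariate raster(s): {missing}")
    ref = rasters[fit.feature_names[0]]
    stack = np.stack([rasters[n].values for n in fit.feature_names], axis=-1)
    flat = stack.reshape(-1, len(fit.feature_names))
    ok = ~np.isnan(flat).any(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if ok.any():
        probs = fit.model.predict_proba(flat[ok])[:, 1]
        out[ok] = np.clip(probs, PREDICTION_FLOOR, 1.0 - 1e-9)
    return CovariateRaster(
        name="OCC",
        values=out.reshape(ref.values.shape),
        origin=ref.origin,
        cell_size=ref.cell_size,
    )
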