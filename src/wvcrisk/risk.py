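"""The multiplicative collision-risk model and its cloglog GLM.

The framework decomposes collision risk on a road segment into exposure
(relative likelihood of species occurrence, O) and hazard (traffic
volume V in vehicles/day and speed S in km/h).  Risk as a rate is

    C_i = exp(b0 + b1 ln O_i + b2 ln V_i + b3 ln S_i)

so that with b1 = b2 = b3 = 1 the rate is exactly proportional to
O * V * S with constant of proportionality a = e^b0.  Treating
collisions as events of a Poisson process, the probability that a
segment records at least one collision is p_i = 1 - exp(-C_i), which
makes the complementary log-log link the natural GLM link:

    cloglog(p_i) = ln(-ln(1 - p_i)) = b0 + b1 ln O_i + b2 ln V_i + b3 ln S_i

Fitting a binomial GLM with this link to binary collision codes
therefore estimates the rate-model coefficients directly, and b1, b2,
b3 measure how far the observed risk departs from exact
proportionality to each component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

__all__ = [
    "RiskCoefficients",
    "CollisionModelFit",
    "cloglog",
    "cloglog_inv",
    "collision_rate",
    "fit_collision_glm",
    "fit_alternative_glm",
    "sequential_deviance_anova",
    "roc_auc",
]

# Floor applied to occurrence probabilities before taking logs; boosted-tree
# probabilities are strictly inside (0,1) but downstream callers may pass 0.
OCCURRENCE_FLOOR = 1e-6


@dataclass(frozen=True)
class RiskCoefficients:
    """Coefficients of the log-linear collision-rate model.

    ``beta0`` is the intercept (ln of the proportionality constant when
    the other coefficients equal one); ``beta1``, ``beta2``, ``beta3``
    multiply ln(occurrence), ln(volume) and ln(speed).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


@dataclass
class CollisionModelFit:
    """A fitted cloglog collision GLM plus its evaluation metrics."""

    coefficients: pd.DataFrame  # index: term; columns: coef, se, z, p
    deviance_explained: float  # percent of null deviance
    aic: float
    anova: pd.Series  # per-term share of total deviance reduction
    terms: list[str]
    result: object = field(repr=False, default=None)  # statsmodels GLMResults
    holdout_roc: float | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted collision probability for a design-matrix frame."""
        exog = sm.add_constant(X[self.terms], has_constant="add")
        return np.asarray(self.result.predict(exog))


def cloglog(p):
    """Complementary log-log link, ln(-ln(1-p)) for p in (0,1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("cloglog requires p strictly inside (0, 1)")
    out = np.log(-np.log1p(-p))
    return float(out) if out.ndim == 0 else out

def cloglog_inv(eta):
    """Inverse link, p = 1 - exp(-exp(eta)); maps any real to (0,1)."""
    eta = np.asarray(eta, dtype=float)
    out = -np.expm1(-np.exp(eta))
    return float(out) if out.ndim == 0 else out


def collision_rate(O, V, S, coefs: RiskCoefficients):
    """Poisson collision rate C = exp(b0 + b1 ln O + b2 ln V + b3 ln S).

    O must lie in (0, 1], V and S must be strictly positive (all three
    enter through logarithms).
    """
    O = np.asarray(O, dtype=float)
    V = np.asarray(V, dtype=float)
    S = np.asarray(S, dtype=float)
    for name, arr in (("O", O), ("V", V), ("S", S)):
        if np.any(arr <= 0):
            bad = np.atleast_1d(arr <= 0)
            raise ValueError(
                f"{name} must be strictly positive for the log-rate model; "
                f"{bad.sum()} offending value(s), first at index "
                f"{int(np.flatnonzero(bad)[0])}"
            )
    if np.any(O > 1):
        raise ValueError("occurrence O must lie in (0, 1]")
    out = np.exp(
        coefs.beta0 + coefs.beta1 * np.log(O) + coefs.beta2 * np.log(V) + coefs.beta3 * np.log(S)
    )
    return float(out) if out.ndim == 0 else out


def _fit_cloglog(y: np.ndarray, X: pd.DataFrame) -> sm.GLM:
    exog = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial(link=sm.families.links.CLogLog()))
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged or np.any(np.abs(res.params) > 1e4):
        raise RuntimeError(
            "cloglog GLM failed to converge (possible complete separation); "
            f"converged={res.converged}, max|coef|={np.max(np.abs(res.params)):.3g}"
        )
    return res


def _summarise(res, terms: list[str], term_order: list[str] | None, y, X) -> CollisionModelFit:
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    dev_expl = 100.0 * (res.null_deviance - res.deviance) / res.null_deviance
    fit = CollisionModelFit(
        coefficients=coef,
        deviance_explained=dev_expl,
        aic=res.aic,
        anova=pd.Series(dtype=float),
        terms=terms,
        result=res,
    )
    fit.anova = sequential_deviance_anova(y, X, term_order or terms)
    return fit


def fit_collision_glm(
    records: pd.DataFrame,
    term_order: list[str] | None = None,
    occurrence_floor: float = OCCURRENCE_FLOOR,
) -> CollisionModelFit:
    """Fit the framework collision model to per-segment records.

    Parameters
    ----------
    records : DataFrame
        Columns ``O`` (occurrence in (0,1]), ``V`` (vehicles/day), ``S``
        (km/h) and binary outcome ``Y``.
    term_order : list of str, optional
        Order in which terms enter the sequential deviance ANOVA;
        defaults to ``["ln_O", "ln_V", "ln_S"]`` (occurrence first).

    Returns
    -------
    CollisionModelFit with raw-scale coefficients on ln O, ln V, ln S.
    """
    y = np.asarray(records["Y"], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both collision and background outcomes are required")
    O = np.clip(np.asarray(records["O"], dtype=float), occurrence_floor, None)
    V = np.asarray(records["V"], dtype=float)
    S = np.asarray(records["S"], dtype=float)
    if np.any(V <= 0) or np.any(S <= 0):
        raise ValueError("V and S must be strictly positive")
    if np.any(O <= 0):
        raise ValueError("O must be strictly positive")
    X = pd.DataFrame({"ln_O": np.log(O), "ln_V": np.log(V), "ln_S": np.log(S)})
    res = _fit_cloglog(y, X)
    return _summarise(res, list(X.columns), term_order, y, X)


def fit_alternative_glm(
    records: pd.DataFrame,
    covariates: list[str],
    term_order: list[str] | None = None,
) -> CollisionModelFit:
    """Fit the flat comparison model: cloglog GLM on raw covariates.

    Instead of the three submodel predictions, the linear predictor uses
    the untransformed covariates directly (one coefficient each).  A
    rank-deficient design (e.g. duplicated columns) is rejected.
    """
    y = np.asarray(records["Y"], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both collision and background outcomes are required")
    X = records[covariates].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < len(covariates) + 1:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {len(covariates) + 1}); "
            "remove aliased covariates"
        )
    res = _fit_cloglog(y, X)
    return _summarise(res, covariates, term_order, y, X)


def sequential_deviance_anova(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    term_order: list[str],
) -> pd.Series:
    """Per-term share of the deviance reduction, terms added in order.

    Refits the GLM with terms 1..k for each k; ``share_k`` is the extra
    deviance drop from adding term k divided by the total drop of the
    full model.  Shares sum to one but depend on the order.
    """
    if sorted(term_order) != sorted(X.columns):
        raise ValueError(
            f"term_order {term_order} is not a permutation of the model terms "
            f"{list(X.columns)}"
        )
    y = np.asarray(y, dtype=float)
    deviances = []
    null_res = sm.GLM(
        y,
        np.ones((len(y), 1)),
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
    ).fit(maxiter=100, tol=1e-8)
    prev = null_res.deviance
    for k in range(1, len(term_order) + 1):
        res = _fit_cloglog(y, X[term_order[:k]])
        deviances.append(prev - res.deviance)
        prev = res.deviance
    drops = np.array(deviances)
    total = drops.sum()
    shares = drops / total if total > 0 else np.full(len(drops), np.nan)
    return pd.Series(shares, index=term_order, name="anova_share")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties between scores count one half.

    Equals the probability that a randomly chosen positive receives a
    higher score than a randomly chosen negative.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC is undefined with a single outcome class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
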