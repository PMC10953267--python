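"""Cross-lagged panel network (CLPN) estimation.

Each T2 variable is regressed on *all* T1 variables with a LASSO penalty;
the resulting directed coefficient matrix ``d`` has autoregressive paths on
the diagonal (a variable predicting itself 18 months later) and cross-lagged
edges off it.  The penalty for each outcome node is tuned by K-fold
cross-validation (minimum mean out-of-fold squared error).  Predictors are
standardized internally during fitting, but coefficients are reported on the
original predictor scale (unstandardized), matching how temporal-network
edge weights are conventionally presented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold

from ._utils import round_half_away
from .errors import ConfigurationError, ConvergenceError, EstimationError

__all__ = [
    "TemporalNetwork",
    "CrossLaggedPanelNetwork",
    "lasso_regression",
    "cv_lambda",
    "fit_clpn",
    "filter_edges",
]


@dataclass
class TemporalNetwork:
    """Directed T1 -> T2 coefficient matrix with per-node tuning metadata.

    ``d[i, j]`` is the coefficient of T1 node ``i`` predicting T2 node ``j``;
    the diagonal holds autoregressive paths.  Each column was fit
    independently (node-wise LASSO), so permuting outcome nodes permutes
    columns of ``d`` and nothing else.
    """

    node_labels: list[str]
    d: np.ndarray
    constructs: dict[str, str] | None = None
    lambda_per_node: np.ndarray | None = None
    cv_seed: int | None = None
    intercepts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        p = len(self.node_labels)
        if d.shape != (p, p):
            raise ConfigurationError(f"d shape {d.shape} != ({p}, {p})")
        self.d = d

    def edge_frame(self, include_autoregressive: bool = True) -> pd.DataFrame:
        rows = []
        p = len(self.node_labels)
        for i in range(p):
            for j in range(p):
                if i == j and not include_autoregressive:
                    continue
                rows.append({"from_node": self.node_labels[i],
                             "to_node": self.node_labels[j],
                             "d": self.d[i, j],
                             "is_autoregressive": i == j})
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise EstimationError("zero-variance predictor column; cannot standardize")
    return (X - mu) / sd, mu, sd


def lasso_regression(y, X, lam: float, max_iter: int = 100000, tol: float = 1e-10):
    """LASSO fit minimizing ``(1/2n) ||y - X b - b0||^2 + lam ||b||_1``.

    The penalty applies on the standardized-predictor scale; the returned
    coefficients are rescaled to the original predictor units, with the
    intercept adjusted accordingly.  Returns ``(coef, intercept)``.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    Xs, mu, sd = _standardize(X)
    if lam == 0.0:
        model = LinearRegression().fit(Xs, y)
        beta_std = model.coef_
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Xs, y)
            except ConvergenceWarning as exc:
                raise ConvergenceError(f"lasso failed to converge: {exc}") from exc
        beta_std = model.coef_
    coef = beta_std / sd
    intercept = float(y.mean() - coef @ mu)
    return coef, intercept


def lasso_lambda_grid(y, X, n_lambdas: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Standard LASSO path: log-spaced from lambda_max (all-zero fit) down."""
    y = np.asarray(y, float).ravel()
    Xs, _, _ = _standardize(np.asarray(X, float))
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def cv_lambda(y, X, folds: int = 10, seed: int = 0, n_lambdas: int = 100,
              min_ratio: float = 1e-3) -> float:
    """Penalty minimizing mean out-of-fold squared error (seeded fold shuffle).

    Deterministic given ``seed``.  Falls back to leave-one-out with a warning
    when there are fewer than ``2 * folds`` observations.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n = len(y)
    if n < 2 * folds:
        warnings.warn(f"n={n} < 2*folds; falling back to leave-one-out", stacklevel=2)
        folds = n
    grid = lasso_lambda_grid(y, X, n_lambdas, min_ratio)
    Xs, _, _ = _standardize(X)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=grid, cv=cv, fit_intercept=True, max_iter=100000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    return float(model.alpha_)


class CrossLaggedPanelNetwork(BaseEstimator):
    """Node-wise cross-validated LASSO estimator of the temporal network.

    ``fit(X_t1, X_t2)`` regresses each T2 column on all T1 columns; each
    outcome gets its own CV-tuned penalty (minimum-CV-error rule, which keeps
    the many small edges a 1-SE rule would eliminate).  One seeded fold
    assignment is shared by all node-wise fits so a refit with the same seed
    is bit-reproducible.

    Attributes
    ----------
    d_ : (p, p) directed coefficient matrix, ``d_[i, j]`` = T1 node i -> T2 node j.
    lambda_per_node_ : selected penalty per outcome node.
    intercepts_ : per-outcome intercepts.
    network_ : the fitted :class:`TemporalNetwork`.
    """

    def __init__(self, cv: int = 10, random_state: int = 0, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-3,
                 constructs: dict[str, str] | None = None,
                 lambdas: dict | None = None):
        self.cv = cv
        self.random_state = random_state
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.constructs = constructs
        self.lambdas = lambdas  # optional per-node overrides {label or index: lam}

    def fit(self, X, y=None):
        """Fit the CLPN.  ``X`` is the T1 matrix; ``y`` the row-aligned T2 matrix."""
        if y is None:
            raise ConfigurationError("CrossLaggedPanelNetwork.fit requires both waves: fit(X_t1, X_t2)")
        X1 = pd.DataFrame(X)
        X2 = pd.DataFrame(y)
        if X1.shape[0] != X2.shape[0]:
            raise ConfigurationError("T1 and T2 matrices must be row-aligned")
        if X1.isna().any().any() or X2.isna().any().any():
            raise ConfigurationError("CLPN input must be listwise-complete across both waves")
        labels = [str(c) for c in X2.columns]
        A1, A2 = X1.to_numpy(float), X2.to_numpy(float)
        n, p = A2.shape
        d = np.zeros((A1.shape[1], p))
        lams = np.zeros(p)
        intercepts = np.zeros(p)
        overrides = self.lambdas or {}
        for j in range(p):
            yj = A2[:, j]
            lam = overrides.get(labels[j], overrides.get(j))
            try:
                if lam is None:
                    lam = cv_lambda(yj, A1, folds=self.cv, seed=self.random_state,
                                    n_lambdas=self.n_lambdas,
                                    min_ratio=self.lambda_min_ratio)
                coef, b0 = lasso_regression(yj, A1, float(lam))
            except ConvergenceError as exc:
                raise ConvergenceError(f"node {labels[j]!r}: {exc}") from exc
            d[:, j] = coef
            lams[j] = lam
            intercepts[j] = b0
        self.d_ = d
        self.lambda_per_node_ = lams
        self.intercepts_ = intercepts
        self.node_labels_ = labels
        self.n_features_in_ = A1.shape[1]
        self.network_ = TemporalNetwork(
            node_labels=labels, d=d, constructs=self.constructs,
            lambda_per_node=lams, cv_seed=self.random_state,
            intercepts=intercepts,
            metadata={"cv_folds": self.cv, "lambda_rule": "min-cv-error",
                      "coefficients": "unstandardized"},
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted T2 scores from T1 scores."""
        A = pd.DataFrame(X).to_numpy(float)
        return A @ self.d_ + self.intercepts_


def fit_clpn(residuals_t1, residuals_t2, seed: int = 0, cv: int = 10,
             constructs: dict[str, str] | None = None,
             lambdas: dict | None = None) -> TemporalNetwork:
    """Thin wrapper over :class:`CrossLaggedPanelNetwork`."""
    est = CrossLaggedPanelNetwork(cv=cv, random_state=seed, constructs=constructs,
                                  lambdas=lambdas)
    est.fit(residuals_t1, residuals_t2)
    return est.network_


def filter_edges(net: TemporalNetwork, threshold: float = 0.01,
                 decimals: int = 2) -> pd.DataFrame:
    """Reporting view: off-diagonal edges with |d| above threshold.

    Sorted by descending edge weight; rounded half-away-from-zero for display
    with raw values retained.
    """
    frame = net.edge_frame(include_autoregressive=False)
    frame = frame[frame["d"].abs() > threshold].copy()
    frame["d_raw"] = frame["d"]
    frame["d"] = frame["d_raw"].map(lambda v: round_half_away(v, decimals))
    frame = frame.sort_values("d_raw", ascending=False, kind="stable").reset_index(drop=True)
    return frame[["from_node", "to_node", "d", "d_raw", "is_autoregressive"]]
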