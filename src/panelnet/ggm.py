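"""Contemporaneous Gaussian graphical model estimation.

A GGM represents each pair of variables by its partial correlation — the
association between two scale scores controlling for all other scores.  The
precision (inverse covariance) matrix Theta is estimated by the graphical
lasso, an L1-penalized maximum-likelihood estimator that shrinks small edges
to exactly zero; the penalty lambda is chosen by minimizing the Extended
Bayesian Information Criterion (EBIC) along a log-spaced lambda path.  Edge
weights are the partial correlations

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj).

The inner solver is block coordinate descent with lasso sub-problems
(scikit-learn's graphical lasso); the path construction and EBIC selection
layer live here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from ._utils import round_half_away
from .errors import ConfigurationError, ConvergenceError, EstimationError

__all__ = [
    "ContemporaneousNetwork",
    "GlassoPathPoint",
    "GaussianGraphicalModel",
    "sample_correlation",
    "graphical_lasso",
    "ebic_score",
    "select_network",
    "average_edges",
]

_ZERO_TOL = 1e-10  # numerical dust below this is a structural zero


def _parse_dual_gap(message: str) -> float | None:
    m = re.search(r"dual gap: (-?[\d.]+e?[-+]?\d*)", message)
    return float(m.group(1)) if m else None


@dataclass
class ContemporaneousNetwork:
    """Symmetric partial-correlation network with its selection metadata."""

    node_labels: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, entries in [-1, 1]
    constructs: dict[str, str] | None = None
    lambda_selected: float = np.nan
    ebic_gamma: float = 0.5
    n_used: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        p = len(self.node_labels)
        if w.shape != (p, p):
            raise ConfigurationError(f"weights shape {w.shape} != ({p}, {p})")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ConfigurationError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        if np.any(np.abs(w) > 1 + 1e-9):
            raise ConfigurationError("partial correlations must lie in [-1, 1]")
        self.weights = w

    def edge_frame(self) -> pd.DataFrame:
        """Upper-triangle edge list as a DataFrame."""
        rows = []
        p = len(self.node_labels)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append({"node_a": self.node_labels[i],
                             "node_b": self.node_labels[j],
                             "weight": self.weights[i, j]})
        return pd.DataFrame(rows)


@dataclass
class GlassoPathPoint:
    lambda_: float
    precision: np.ndarray
    log_likelihood: float
    edge_count: int
    ebic: float


def sample_correlation(residuals, wave: str | None = None,
                       wave_suffixes: dict[str, str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix on listwise-complete rows.

    When ``wave`` is given, columns carrying that wave's suffix are selected
    (and the suffix stripped from the labels).
    """
    df = pd.DataFrame(residuals)
    if wave is not None:
        suffixes = wave_suffixes or {"T1": "_t1", "T2": "_t2"}
        suf = suffixes[wave]
        cols = [c for c in df.columns if str(c).endswith(suf)]
        if not cols:
            raise ConfigurationError(f"no columns with suffix {suf!r} for wave {wave}")
        df = df[cols].rename(columns={c: str(c)[: -len(suf)] for c in cols})
    df = df.dropna()
    if len(df) < 10:
        raise EstimationError(f"need at least 10 complete rows, have {len(df)}")
    sds = df.std(ddof=1)
    degenerate = sds[sds == 0].index.tolist()
    if degenerate:
        raise EstimationError(f"zero-variance column(s): {degenerate}")
    return df.corr()


def graphical_lasso(S, lam: float, tol: float = 1e-5, max_iter: int = 500,
                    enet_tol: float | None = None) -> np.ndarray:
    """Penalized precision-matrix estimate for one penalty value.

    Maximizes ``log det Theta - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|``.
    ``lam = 0`` reduces to direct inversion of S.  ``tol`` is the duality-gap
    convergence threshold of the block coordinate-descent solver; a residual
    gap slightly above it near the small-lambda end of a path is tolerated
    (it is far below the sampling noise of any edge), but a gap that stays
    large is a convergence error.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    if lam == 0.0:
        return np.linalg.inv(S)
    try:
        if enet_tol is None:
            enet_tol = min(1e-4, tol)  # inner lasso accuracy bounds the outer one
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            _, precision = _sk_graphical_lasso(S, alpha=lam, tol=tol,
                                               enet_tol=enet_tol, max_iter=max_iter)
        for w in caught:
            gap = _parse_dual_gap(str(w.message))
            if gap is not None and abs(gap) > max(1e-2, 100 * tol):
                raise ConvergenceError(
                    f"graphical lasso did not converge at lambda={lam:.5g}: "
                    f"duality gap {gap:.3g}"
                )
    except FloatingPointError as exc:  # pragma: no cover - pathological input
        raise ConvergenceError(f"graphical lasso failed to converge: {exc}") from exc
    precision = np.asarray(precision, dtype=float)
    off_dust = (np.abs(precision) < _ZERO_TOL) & ~np.eye(precision.shape[0], dtype=bool)
    precision[off_dust] = 0.0
    return precision


def glasso_objective(precision, S, lam: float) -> float:
    """The (negated) penalized log-likelihood being minimized; used by oracles too."""
    precision = np.asarray(precision, float)
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    off = precision - np.diag(np.diag(precision))
    return float(-logdet + np.trace(S @ precision) + lam * np.abs(off).sum())


def _edge_count(precision: np.ndarray) -> int:
    off = np.triu(precision, k=1)
    return int(np.count_nonzero(np.abs(off) > _ZERO_TOL))


def ebic_score(precision, S, n: int, gamma: float, edge_count: int | None = None) -> float:
    """Extended BIC: ``-2 ll + E log n + 4 E gamma log p`` with ``E`` edges, ``p`` nodes.

    ``gamma = 0`` reduces to the ordinary BIC; larger gamma favours sparser
    networks.
    """
    precision = np.asarray(precision, float)
    S = np.asarray(S, float)
    p = S.shape[0]
    E = _edge_count(precision) if edge_count is None else edge_count
    sign, logdet = np.linalg.slogdet(precision)
    ll = 0.5 * n * (logdet - np.trace(S @ precision))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_partial(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix; structural zeros preserved."""
    d = np.sqrt(np.diag(precision))
    partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    partial[np.abs(precision) <= _ZERO_TOL] = 0.0
    np.fill_diagonal(partial, 0.0)
    return partial


def lambda_grid(S, n_lambdas: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from lambda_max (empty graph) down to min_ratio * lambda_max."""
    S = np.asarray(S, float)
    lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def select_network(
    S,
    n: int,
    gamma: float = 0.5,
    lambdas=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    node_labels: list[str] | None = None,
    constructs: dict[str, str] | None = None,
    return_path: bool = False,
):
    """EBIC-minimizing network along a graphical-lasso path.

    Ties in EBIC break toward the larger (sparser) penalty: the path is
    scanned from lambda_max downward and a point must strictly improve EBIC
    to be preferred.
    """
    if isinstance(S, pd.DataFrame):
        node_labels = node_labels or [str(c) for c in S.columns]
        S = S.to_numpy(float)
    S = np.asarray(S, float)
    p = S.shape[0]
    node_labels = node_labels or [f"v{i}" for i in range(p)]
    lambdas = np.sort(np.asarray(
        lambda_grid(S, n_lambdas, lambda_min_ratio) if lambdas is None else lambdas,
        dtype=float))[::-1]

    path: list[GlassoPathPoint] = []
    best = None
    for lam in lambdas:
        precision = graphical_lasso(S, float(lam))
        E = _edge_count(precision)
        sign, logdet = np.linalg.slogdet(precision)
        ll = 0.5 * n * (logdet - np.trace(S @ precision))
        ebic = ebic_score(precision, S, n, gamma, edge_count=E)
        point = GlassoPathPoint(float(lam), precision, float(ll), E, float(ebic))
        path.append(point)
        if best is None or point.ebic < best.ebic:
            best = point

    net = ContemporaneousNetwork(
        node_labels=node_labels,
        weights=precision_to_partial(best.precision),
        constructs=constructs,
        lambda_selected=best.lambda_,
        ebic_gamma=gamma,
        n_used=int(n),
        metadata={
            "n_lambdas": len(lambdas),
            "lambda_min_ratio": float(lambdas[-1] / lambdas[0]),
            "correlation": "pearson",
            "edge_count": best.edge_count,
        },
    )
    return (net, path) if return_path else net


class GaussianGraphicalModel(BaseEstimator):
    """EBIC-tuned graphical-lasso estimator of a partial-correlation network.

    scikit-learn style: ``fit(X)`` on an (n, p) matrix of continuous
    (typically covariate-residualized) scale scores.

    Parameters
    ----------
    gamma : EBIC hyperparameter (0 = plain BIC; 0.5 is the conventional
        default for psychological networks).
    n_lambdas, lambda_min_ratio : penalty-path geometry.
    rank_correlation : when True, Pearson correlations are replaced by the
        normal-transform of Spearman correlations (for raw ordinal inputs).

    Attributes
    ----------
    correlation_ : (p, p) input correlation matrix.
    precision_ : selected penalized precision matrix.
    partial_corr_ : selected partial-correlation weights (zero diagonal).
    lambda_ : selected penalty.
    path_ : list of :class:`GlassoPathPoint` along the penalty path.
    network_ : the fitted :class:`ContemporaneousNetwork`.
    """

    def __init__(self, gamma: float = 0.5, n_lambdas: int = 100,
                 lambda_min_ratio: float = 0.01, rank_correlation: bool = False,
                 constructs: dict[str, str] | None = None):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rank_correlation = rank_correlation
        self.constructs = constructs

    def fit(self, X, y=None):
        df = pd.DataFrame(X).dropna()
        labels = [str(c) for c in df.columns]
        if self.rank_correlation:
            S = np.sin(np.pi / 6 * df.corr(method="spearman").to_numpy()) * 2
            S = np.clip(S, -1, 1)
            np.fill_diagonal(S, 1.0)
        else:
            S = sample_correlation(df).to_numpy()
        self.correlation_ = S
        self.n_features_in_ = S.shape[0]
        net, path = select_network(
            S, n=len(df), gamma=self.gamma, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio, node_labels=labels,
            constructs=self.constructs, return_path=True,
        )
        self.network_ = net
        self.path_ = path
        self.partial_corr_ = net.weights
        self.lambda_ = net.lambda_selected
        self.precision_ = next(pt.precision for pt in path if pt.lambda_ == net.lambda_selected)
        return self


def average_edges(
    net_t1: ContemporaneousNetwork,
    net_t2: ContemporaneousNetwork,
    threshold: float = 0.01,
    filter_rule: str = "either_wave",
    decimals: int = 2,
) -> pd.DataFrame:
    """Cross-wave averaged edge table: per pair, ``(w_T1 + w_T2) / 2``.

    Rounded half-away-from-zero for display; unrounded values are kept in
    ``*_raw`` columns.  ``filter_rule='either_wave'`` keeps pairs whose
    weight exceeds the threshold in absolute value at either wave;
    ``'average'`` filters on the averaged weight instead.
    """
    if net_t1.node_labels != net_t2.node_labels:
        raise ConfigurationError("node labels differ between the two networks")
    rows = []
    labels = net_t1.node_labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            w1, w2 = net_t1.weights[i, j], net_t2.weights[i, j]
            avg = (w1 + w2) / 2.0
            if filter_rule == "either_wave":
                keep = abs(w1) > threshold or abs(w2) > threshold
            elif filter_rule == "average":
                keep = abs(avg) > threshold
            else:
                raise ConfigurationError(f"unknown filter_rule {filter_rule!r}")
            if keep:
                rows.append({
                    "node_a": labels[i], "node_b": labels[j],
                    "weight_t1": round_half_away(w1, decimals),
                    "weight_t2": round_half_away(w2, decimals),
                    "weight_avg": round_half_away(avg, decimals),
                    "weight_t1_raw": w1, "weight_t2_raw": w2, "weight_avg_raw": avg,
                })
    out = pd.DataFrame(rows, columns=["node_a", "node_b", "weight_t1", "weight_t2",
                                      "weight_avg", "weight_t1_raw", "weight_t2_raw",
                                      "weight_avg_raw"])
    return out.sort_values("weight_avg_raw", ascending=False, kind="stable").reset_index(drop=True)
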