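"""Centrality indices for contemporaneous and temporal networks.

For the undirected (contemporaneous) network the index is expected
influence, EI(i) = sum over j != i of w_ij — a *signed* sum, so a node with
strong negative edges is pulled down rather than up (unlike strength, which
sums absolute values).

For the directed (temporal) network, in-prediction of node j sums the
permitted incoming coefficients d[i, j] and out-prediction of node i sums
the permitted outgoing coefficients d[i, j]:

* ``cross_lagged``   — all edges except the node's autoregressive path;
* ``cross_construct`` — additionally excludes edges within the node's own
  construct (parenting vs mental health), isolating the influence that
  crosses between the parenting and mental-health domains.

A variance-explained reading of in-prediction — the proportion of a T2
node's variance accounted for by the permitted T1 predictors — is offered as
a separate, explicitly labeled operation; neither reading is silently
preferred in exports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clpn import TemporalNetwork
from .errors import ConfigurationError
from .ggm import ContemporaneousNetwork

__all__ = [
    "expected_influence",
    "in_prediction",
    "out_prediction",
    "variance_explained_prediction",
    "temporal_centrality_table",
]

VARIANTS = ("cross_lagged", "cross_construct")


def _table(nodes, values, index_type: str, variant: str) -> pd.DataFrame:
    return pd.DataFrame({
        "node": list(nodes),
        "index_type": index_type,
        "variant": variant,
        "value": np.asarray(values, float),
    })


def expected_influence(net: ContemporaneousNetwork) -> pd.DataFrame:
    """One-step expected influence: signed row sums of the weight matrix."""
    ei = net.weights.sum(axis=1)  # diagonal is structurally zero
    return _table(net.node_labels, ei, "EI", "none")


def _permitted_mask(net: TemporalNetwork, variant: str) -> np.ndarray:
    """Boolean (p, p) mask of permitted directed edges i -> j."""
    p = len(net.node_labels)
    if variant not in VARIANTS:
        raise ConfigurationError(f"variant must be one of {VARIANTS}, got {variant!r}")
    mask = ~np.eye(p, dtype=bool)  # autoregressive paths always excluded
    if variant == "cross_construct":
        if not net.constructs:
            raise ConfigurationError("cross_construct variant requires construct tags")
        try:
            tags = [net.constructs[lbl] for lbl in net.node_labels]
        except KeyError as exc:
            raise ConfigurationError(f"unknown construct tag for node {exc}") from exc
        same = np.equal.outer(np.asarray(tags, object), np.asarray(tags, object))
        mask &= ~same
    return mask


def in_prediction(net: TemporalNetwork, variant: str = "cross_lagged") -> pd.DataFrame:
    """Signed sum of permitted incoming edges per T2 node."""
    mask = _permitted_mask(net, variant)
    values = np.where(mask, net.d, 0.0).sum(axis=0)
    return _table(net.node_labels, values, "in_prediction", variant)


def out_prediction(net: TemporalNetwork, variant: str = "cross_lagged") -> pd.DataFrame:
    """Signed sum of permitted outgoing edges per T1 node."""
    mask = _permitted_mask(net, variant)
    values = np.where(mask, net.d, 0.0).sum(axis=1)
    return _table(net.node_labels, values, "out_prediction", variant)


def variance_explained_prediction(
    net: TemporalNetwork, residuals_t1, residuals_t2, variant: str = "cross_lagged"
) -> pd.DataFrame:
    """In-prediction as variance explained.

    For each T2 node j, the fitted linear predictor is restricted to the
    permitted T1 predictors (non-permitted coefficients zeroed) and the
    index is the squared correlation between the observed T2 scores and that
    restricted predictor — a proportion of variance in [0, 1] that can never
    exceed the R^2 of the unrestricted least-squares fit.  All-zero permitted
    coefficients give 0.
    """
    X1 = pd.DataFrame(residuals_t1).to_numpy(float)
    X2 = pd.DataFrame(residuals_t2).to_numpy(float)
    p = len(net.node_labels)
    if X1.shape[0] != X2.shape[0] or X1.shape[1] != p or X2.shape[1] != p:
        raise ConfigurationError("residual matrices do not match the fitted network")
    mask = _permitted_mask(net, variant)
    values = np.zeros(p)
    for j in range(p):
        coef = np.where(mask[:, j], net.d[:, j], 0.0)
        if not np.any(coef):
            values[j] = 0.0
            continue
        yhat = X1 @ coef
        y = X2[:, j]
        if np.std(yhat) == 0 or np.std(y) == 0:
            values[j] = 0.0
        else:
            values[j] = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return _table(net.node_labels, values, "in_prediction_r2", variant)


def temporal_centrality_table(net: TemporalNetwork) -> pd.DataFrame:
    """All four signed-sum temporal centralities in one tidy table."""
    parts = [fn(net, variant)
             for variant in VARIANTS
             for fn in (in_prediction, out_prediction)]
    return pd.concat(parts, ignore_index=True)
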