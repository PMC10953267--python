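"""Layout computation and network/table exports (CSV, GraphML, JSON).

The canonical outputs are data, not pictures: edge tables in the layout of
the printed report tables, GraphML with construct/weight attributes for any
renderer, and a shared force-directed layout so the two contemporaneous
networks can be drawn with each node at the same position in both.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pandas as pd

from .clpn import TemporalNetwork
from .errors import ConfigurationError
from .ggm import ContemporaneousNetwork

__all__ = [
    "average_layout",
    "contemporaneous_graph",
    "temporal_graph",
    "export_graphml",
    "export_json_adjacency",
]


def average_layout(net_t1: ContemporaneousNetwork, net_t2: ContemporaneousNetwork,
                   seed: int = 0) -> pd.DataFrame:
    """Shared Fruchterman-Reingold layout on the mean absolute weight matrix.

    Computed once on ``(|W_T1| + |W_T2|) / 2`` so the same node lands at the
    same coordinates in both networks; coordinates normalized to the unit
    square.  Deterministic given the seed (an empty averaged network still
    yields a deterministic seeded placement).
    """
    if net_t1.node_labels != net_t2.node_labels:
        raise ConfigurationError("layout requires identical node sets")
    A = (np.abs(net_t1.weights) + np.abs(net_t2.weights)) / 2.0
    G = nx.from_numpy_array(A)
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    xy = np.array([pos[i] for i in range(len(net_t1.node_labels))], float)
    for k in range(2):
        lo, hi = xy[:, k].min(), xy[:, k].max()
        xy[:, k] = 0.5 if hi - lo < 1e-12 else (xy[:, k] - lo) / (hi - lo)
    return pd.DataFrame({"node": net_t1.node_labels, "x": xy[:, 0], "y": xy[:, 1]})


def contemporaneous_graph(net: ContemporaneousNetwork) -> nx.Graph:
    G = nx.Graph()
    for lbl in net.node_labels:
        G.add_node(lbl, construct=(net.constructs or {}).get(lbl, ""))
    p = len(net.node_labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0.0:
                G.add_edge(net.node_labels[i], net.node_labels[j], weight=float(w))
    return G


def temporal_graph(net: TemporalNetwork) -> nx.DiGraph:
    """Directed graph; autoregressive self-loops are flagged so renderers can hide them."""
    G = nx.DiGraph()
    for lbl in net.node_labels:
        G.add_node(lbl, construct=(net.constructs or {}).get(lbl, ""))
    p = len(net.node_labels)
    for i in range(p):
        for j in range(p):
            w = net.d[i, j]
            if w != 0.0:
                G.add_edge(net.node_labels[i], net.node_labels[j],
                           weight=float(w), is_autoregressive=bool(i == j))
    return G


def export_graphml(net, path) -> None:
    G = (temporal_graph(net) if isinstance(net, TemporalNetwork)
         else contemporaneous_graph(net))
    nx.write_graphml(G, path)


def export_json_adjacency(net, path=None) -> str:
    matrix = net.d if isinstance(net, TemporalNetwork) else net.weights
    payload = json.dumps({
        "directed": isinstance(net, TemporalNetwork),
        "nodes": list(net.node_labels),
        "constructs": net.constructs or {},
        "weights": np.asarray(matrix, float).tolist(),
    }, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload
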