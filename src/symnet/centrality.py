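"""Node centrality and bridge-centrality indices for weighted networks.

Indices follow the conventions of network psychometrics:

* strength: sum of absolute edge weights at a node;
* expected influence (one-step, ``ei1``): signed sum of edge weights;
* expected influence (two-step, ``ei2``): ``ei1`` plus the weight-weighted
  sum of neighbours' one-step expected influence;
* closeness / betweenness: computed on shortest paths with edge distances
  ``1 / |w|`` over nonzero edges (strong edges are short);
* bridge expected influence (one-step, ``bei1``): signed sum of a node's
  edges into *other* communities;
* bridge expected influence (two-step, ``bei2``): ``bei1`` plus indirect
  influence through neighbours' own cross-community connectivity:

      bei2_i = bei1_i + sum_{j != i} w_ij * sum_{k not in c(i), k != i} w_jk.

Bridge nodes are the top fraction (default 25%) of nodes by ``bei2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["compute_centrality", "bridge_expected_influence",
           "select_bridges", "BridgeResult"]


def _as_weights(net) -> tuple[np.ndarray, list[str]]:
    if hasattr(net, "weights") and hasattr(net, "node_names"):
        return np.asarray(net.weights, dtype=float), list(net.node_names)
    W = np.asarray(net, dtype=float)
    return W, [f"X{i + 1}" for i in range(W.shape[0])]


def _distance_graph(W: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    p = W.shape[0]
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0.0:
                G.add_edge(i, j, distance=1.0 / abs(W[i, j]))
    return G


def compute_centrality(net, communities: dict[str, str] | None = None,
                       ) -> pd.DataFrame:
    """Centrality table for a symmetric weighted network.

    Parameters
    ----------
    net : EstimatedNetwork, IsingGraph-like, or (p, p) array
        Anything with ``.weights``/``.node_names``, or a plain matrix.
    communities : dict, optional
        ``node -> community``; when given, bridge expected influence
        columns (``bei1``, ``bei2``) are included.

    Returns
    -------
    DataFrame indexed by node with raw indices and z-standardized copies
    (columns prefixed ``z_``).  Path-based indices of isolated nodes (and
    of every node in an empty network) are 0; closeness is computed within
    each node's connected component and a ``component`` column flags
    disconnected structure.
    """
    W, names = _as_weights(net)
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    p = W.shape[0]
    absW = np.abs(W)
    strength = absW.sum(axis=1)
    ei1 = W.sum(axis=1)
    ei2 = ei1 + W @ ei1

    G = _distance_graph(W)
    if G.number_of_edges() == 0:
        warnings.warn("empty network: path-based centralities set to 0",
                      RuntimeWarning)
    closeness = np.zeros(p)
    comp_id = np.zeros(p, dtype=int)
    for ci, comp in enumerate(nx.connected_components(G)):
        for i in comp:
            comp_id[i] = ci
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for i, dists in nx.shortest_path_length(sub, weight="distance"):
            closeness[i] = 1.0 / sum(d for j, d in dists.items() if j != i)
    betweenness = np.zeros(p)
    if G.number_of_edges() > 0:
        bc = nx.betweenness_centrality(G, weight="distance", normalized=False)
        for i, v in bc.items():
            betweenness[i] = v

    out = pd.DataFrame({
        "strength": strength,
        "closeness": closeness,
        "betweenness": betweenness,
        "ei1": ei1,
        "ei2": ei2,
    }, index=pd.Index(names, name="node"))
    if communities is not None:
        bei1, bei2 = bridge_expected_influence(net, communities)
        out["bei1"] = bei1
        out["bei2"] = bei2
    for col in list(out.columns):
        sd = out[col].std(ddof=1)
        out["z_" + col] = (out[col] - out[col].mean()) / sd if sd > 0 else 0.0
    out["component"] = comp_id
    return out


def bridge_expected_influence(net, communities: dict[str, str],
                              ) -> tuple[pd.Series, pd.Series]:
    """One- and two-step bridge expected influence per node.

    ``bei1`` sums a node's signed edge weights into other communities;
    ``bei2`` adds indirect influence routed through any neighbour's own
    cross-community edges (relative to the origin node's community).
    """
    W, names = _as_weights(net)
    p = W.shape[0]
    missing = [c for c in names if c not in communities]
    if missing:
        raise ValueError(f"no community assigned to node(s): {missing}")
    comm = np.array([communities[c] for c in names], dtype=object)

    bei1 = np.zeros(p)
    bei2 = np.zeros(p)
    for i in range(p):
        outside = comm != comm[i]
        bei1[i] = W[i, outside].sum()
        mask = outside.copy()
        mask[i] = False  # k != i (redundant given i's own community, explicit)
        indirect = 0.0
        for j in range(p):
            if j == i or W[i, j] == 0.0:
                continue
            indirect += W[i, j] * W[j, mask].sum()
        bei2[i] = bei1[i] + indirect
    idx = pd.Index(names, name="node")
    return pd.Series(bei1, index=idx, name="bei1"), \
        pd.Series(bei2, index=idx, name="bei2")


@dataclass
class BridgeResult:
    """Bridge-node selection: the top-fraction nodes by bridge EI."""

    selected: list[str]
    rule: float
    scores: pd.Series

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        return {"selected": self.selected, "fraction": self.rule,
                "scores": {k: float(v) for k, v in self.scores.items()}}


def select_bridges(scores: pd.Series, fraction: float = 0.25) -> BridgeResult:
    """Select the ceil(fraction * p) highest-scoring nodes as bridges.

    Ties at the selection boundary are broken by node order (earlier nodes
    win) with a warning, so the count is always exactly ceil(fraction * p).
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(np.asarray(scores, dtype=float),
                           index=[f"X{i + 1}" for i in range(len(scores))])
    p = len(scores)
    if p < 1:
        raise ValueError("scores must be non-empty")
    k = math.ceil(fraction * p)
    # stable sort: descending score, ties by original node order
    order = np.lexsort((np.arange(p), -scores.to_numpy()))
    cut = scores.iloc[order[k - 1]]
    if k < p and scores.iloc[order[k]] == cut:
        warnings.warn(
            f"tie at the bridge selection boundary (score {cut}); "
            "broken by node order", RuntimeWarning,
        )
    selected = [scores.index[i] for i in order[:k]]
    return BridgeResult(selected=selected, rule=fraction, scores=scores)
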