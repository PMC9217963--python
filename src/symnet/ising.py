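"""Sparse Ising network estimation by nodewise l1-logistic regression
("eLasso") with extended-BIC model selection.

Each binary node is regressed on all remaining nodes along a decreasing
penalty path; the model minimizing the extended Bayesian Information
Criterion

    EBIC = -2 loglik + k ln(n) + 2 gamma k ln(p - 1)

is selected per node (k = nonzero slope count), and the two directed
coefficient estimates for every pair are symmetrized into one undirected
edge weight (AND rule by default: the edge exists only if both directed
regressions retain it; weight = mean of the two coefficients).  Edge
weights are conditional log-odds-ratios and can be read like partial
correlations: an edge is an association that survives conditioning on all
other nodes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._solvers import logistic_lasso_path, logistic_lambda_max
from .data import ItemMatrix
from .network import EstimatedNetwork, EstimationSettings

__all__ = ["IsingModel", "IsingResults", "ebic", "fit_nodewise_path",
           "select_by_ebic", "assemble_network"]

_COEF_SNAP = 1e-10  # coefficients below this are numerically zero


def ebic(loglik: float, k: int, n: int, p_other: int, gamma: float) -> float:
    """Extended Bayesian Information Criterion.

    Parameters
    ----------
    loglik : float
        Log-likelihood of the fitted model.
    k : int
        Number of nonzero (penalized) coefficients.
    n : int
        Sample size.
    p_other : int
        Number of candidate predictors.
    gamma : float
        Sparsity hyperparameter; gamma = 0 recovers the ordinary BIC.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    extra = 2.0 * gamma * k * np.log(p_other) if k > 0 else 0.0
    return -2.0 * loglik + k * np.log(n) + extra


def fit_nodewise_path(items, node, settings: EstimationSettings | None = None):
    """l1-logistic path of one node regressed on all remaining columns.

    Parameters
    ----------
    items : ItemMatrix or DataFrame
        Binary data table.
    node : int or str
        Response column (index or name).
    settings : EstimationSettings

    Returns
    -------
    dict with keys ``lambdas``, ``coefs`` (L x (p-1)), ``intercepts``,
    ``logliks``, ``predictors`` (column names), ``truncated`` (bool).
    The penalty grid runs log-spaced from the node's lambda_max (smallest
    penalty with an all-zero slope vector) down to
    ``lambda_max * lambda_min_ratio``.
    """
    settings = settings or EstimationSettings()
    values = items.values if isinstance(items, ItemMatrix) else pd.DataFrame(items)
    if isinstance(node, str):
        node_name = node
    else:
        node_name = values.columns[node]
    y = values[node_name].to_numpy(dtype=float)
    if y.min() < 0 or y.max() > 1 or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"node {node_name!r} is not binary 0/1")
    if y.min() == y.max():
        raise ValueError(f"node {node_name!r} is constant")
    predictors = [c for c in values.columns if c != node_name]
    X = values[predictors].to_numpy(dtype=float)

    lam_max = logistic_lambda_max(X, y)
    if lam_max <= 0:  # response uncorrelated with everything (degenerate)
        lam_max = 1e-4
    lambdas = np.geomspace(lam_max, lam_max * settings.lambda_min_ratio,
                           settings.n_lambda)
    betas, intercepts, logliks, n_valid = logistic_lasso_path(X, y, lambdas)
    truncated = n_valid < len(lambdas)
    if truncated:
        warnings.warn(
            f"node {node_name!r}: path truncated at {n_valid}/{len(lambdas)} "
            "penalties (coefficients diverged; quasi-separation)",
            RuntimeWarning,
        )
        if n_valid == 0:
            raise RuntimeError(f"node {node_name!r}: no penalty converged")
    betas = betas[:n_valid]
    betas[np.abs(betas) < _COEF_SNAP] = 0.0
    return {
        "node": node_name,
        "predictors": predictors,
        "lambdas": lambdas[:n_valid],
        "coefs": betas,
        "intercepts": intercepts[:n_valid],
        "logliks": logliks[:n_valid],
        "truncated": truncated,
    }


def select_by_ebic(path: dict, n: int, gamma: float) -> dict:
    """Pick the penalty minimizing the EBIC along one node's path.

    Ties favor the larger penalty (sparser model).  Returns the selection:
    ``{"coef": Series by predictor, "intercept", "lambda", "ebic", "k"}``.
    """
    p_other = len(path["predictors"])
    ks = (np.abs(path["coefs"]) > 0).sum(axis=1)
    crit = np.array([
        ebic(ll, int(k), n, p_other, gamma)
        for ll, k in zip(path["logliks"], ks)
    ])
    best = int(np.argmin(crit))
    return {
        "node": path["node"],
        "coef": pd.Series(path["coefs"][best], index=path["predictors"]),
        "intercept": float(path["intercepts"][best]),
        "lambda": float(path["lambdas"][best]),
        "ebic": float(crit[best]),
        "k": int(ks[best]),
        "ebic_path": crit,
    }


def assemble_network(per_node_selections: dict, settings: EstimationSettings,
                     node_names: list[str],
                     extra_settings: dict | None = None) -> EstimatedNetwork:
    """Symmetrize per-node selected coefficient vectors into one network.

    ``per_node_selections`` maps node name -> selection dict (or ``None``
    for nodes skipped as constant, whose edges are recorded absent).
    Under the AND rule an edge (i, j) requires both directed coefficients
    nonzero and its weight is their mean; under OR one suffices, with zero
    substituted for the missing coefficient.
    """
    p = len(node_names)
    coef = np.zeros((p, p))  # coef[i, j]: effect of j in the regression of i
    thresholds = np.zeros(p)
    for i, name in enumerate(node_names):
        sel = per_node_selections.get(name)
        if sel is None:
            continue
        missing = set(sel["coef"].index) - set(node_names)
        if missing or len(sel["coef"]) != p - 1:
            raise ValueError(f"selection for node {name!r} does not match "
                             "the network's node set")
        thresholds[i] = sel["intercept"]
        for j, other in enumerate(node_names):
            if other != name:
                coef[i, j] = sel["coef"][other]

    weights = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = coef[i, j], coef[j, i]
            if settings.rule == "AND":
                w = 0.5 * (a + b) if (a != 0.0 and b != 0.0) else 0.0
            else:  # OR
                w = 0.5 * (a + b) if (a != 0.0 or b != 0.0) else 0.0
            weights[i, j] = weights[j, i] = w

    meta = settings.to_dict()
    meta.update(extra_settings or {})
    return EstimatedNetwork(weights, thresholds, node_names, settings=meta)


class IsingModel:
    """Ising network model for a binary item matrix (eLasso estimation).

    Parameters
    ----------
    data : ItemMatrix or DataFrame
        Participants x nodes table of 0/1 items.
    settings : EstimationSettings, optional
    **settings_kwargs
        Convenience overrides (``gamma=0.5``, ``rule="OR"``, ...).

    Examples
    --------
    >>> model = IsingModel(items, gamma=0.25)
    >>> res = model.fit()
    >>> res.weights            # symmetric edge-weight matrix
    >>> res.summary()
    """

    def __init__(self, data, settings: EstimationSettings | None = None,
                 **settings_kwargs):
        if settings is not None and settings_kwargs:
            raise ValueError("pass either settings or keyword overrides")
        self.settings = settings or EstimationSettings(**settings_kwargs)
        if isinstance(data, ItemMatrix):
            bad = data.continuous_nodes()
            if bad:
                raise ValueError(
                    f"IsingModel requires binary nodes; continuous: {bad} "
                    "(dichotomize them or use MixedGraphicalModel)"
                )
            self.data = data.values
        else:
            self.data = pd.DataFrame(data)
        arr = self.data.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("IsingModel data must be binary 0/1")
        self.node_names = list(self.data.columns)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "IsingModel":
        return cls(frame, **kwargs)

    @property
    def n(self) -> int:
        return len(self.data)

    def fit(self) -> "IsingResults":
        """Estimate the network; returns an :class:`IsingResults`."""
        selections: dict = {}
        skipped: list[str] = []
        for name in self.node_names:
            col = self.data[name].to_numpy()
            if col.min() == col.max():
                if self.settings.on_constant == "skip":
                    selections[name] = None
                    skipped.append(name)
                    continue
                raise ValueError(f"node {name!r} is constant")
            path = fit_nodewise_path(self.data, name, self.settings)
            selections[name] = select_by_ebic(path, self.n, self.settings.gamma)
        net = assemble_network(
            selections, self.settings, self.node_names,
            extra_settings={"engine": "ising_elasso", "n": self.n,
                            "skipped_nodes": skipped},
        )
        return IsingResults(self, net, selections)


class IsingResults(EstimatedNetwork):
    """Fitted Ising network: weights, thresholds, selection diagnostics."""

    def __init__(self, model: IsingModel, net: EstimatedNetwork, selections):
        super().__init__(net.weights, net.thresholds, net.node_names,
                         net.settings)
        self.model = model
        self.selections = selections

    def selection_table(self) -> pd.DataFrame:
        """Per-node selected penalty, EBIC and nonzero-coefficient count."""
        rows = []
        for name in self.node_names:
            sel = self.selections.get(name)
            if sel is None:
                rows.append((name, np.nan, np.nan, 0, True))
            else:
                rows.append((name, sel["lambda"], sel["ebic"], sel["k"], False))
        return pd.DataFrame(rows, columns=["node", "lambda", "ebic", "k",
                                           "skipped"]).set_index("node")

    def centrality(self, communities: dict[str, str] | None = None):
        """Centrality table (see :func:`symnet.centrality.compute_centrality`)."""
        from .centrality import compute_centrality
        return compute_centrality(self, communities=communities)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Ising network (eLasso, EBIC selection)",
            "=" * 42,
            f"nodes:            {self.p}",
            f"observations:     {self.settings.get('n', self.model.n)}",
            f"gamma:            {self.settings.get('gamma')}",
            f"rule:             {self.settings.get('rule')}",
            f"possible edges:   {self.n_possible_edges}",
            f"nonzero edges:    {self.n_edges} "
            f"({100 * self.n_edges / self.n_possible_edges:.0f}%)",
            f"mean |weight|:    {self.mean_abs_weight():.2f}",
        ]
        if self.settings.get("skipped_nodes"):
            lines.append(f"skipped (constant): {self.settings['skipped_nodes']}")
        return "\n".join(lines)
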