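"""Pairwise mixed graphical model (MGM) via nodewise penalized regression.

Sensitivity-analysis estimator for networks mixing binary symptom items
with continuous risk factors: every node is regressed on all others with a
family matched to its scale (l1-logistic for binary, l1-linear for
continuous), the EBIC selects each node's penalty, and edges are
symmetrized exactly as in the Ising estimator.  Continuous columns are
standardized internally (mean 0, sd 1), so cross-family weights are on the
standardized-predictor conditional-logit scale and are not directly
comparable to pure Ising weights; with an all-binary input the estimator
reduces to the Ising eLasso.  Only pairwise interactions are modelled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._solvers import (gaussian_lambda_max, gaussian_lasso_path,
                       logistic_lambda_max, logistic_lasso_path)
from .data import ItemMatrix
from .ising import _COEF_SNAP, assemble_network, ebic, select_by_ebic
from .network import EstimatedNetwork, EstimationSettings

__all__ = ["MixedGraphicalModel", "MGMResults", "fit_mgm"]


def _gaussian_path(values: pd.DataFrame, node: str,
                   settings: EstimationSettings) -> dict:
    predictors = [c for c in values.columns if c != node]
    X = values[predictors].to_numpy(dtype=float)
    y = values[node].to_numpy(dtype=float)
    lam_max = gaussian_lambda_max(X, y)
    if lam_max <= 0:
        lam_max = 1e-4
    lambdas = np.geomspace(lam_max, lam_max * settings.lambda_min_ratio,
                           settings.n_lambda)
    betas, intercepts, logliks, n_valid = gaussian_lasso_path(X, y, lambdas)
    betas[np.abs(betas) < _COEF_SNAP] = 0.0
    return {
        "node": node,
        "predictors": predictors,
        "lambdas": lambdas,
        "coefs": betas,
        "intercepts": intercepts,
        "logliks": logliks,
        "truncated": False,
    }


def _logistic_path(values: pd.DataFrame, node: str,
                   settings: EstimationSettings) -> dict:
    # same path construction as the Ising estimator, but predictors may be
    # continuous; reuse the nodewise fit through the raw solver to avoid the
    # binary-predictor validation
    predictors = [c for c in values.columns if c != node]
    X = values[predictors].to_numpy(dtype=float)
    y = values[node].to_numpy(dtype=float)
    lam_max = logistic_lambda_max(X, y)
    if lam_max <= 0:
        lam_max = 1e-4
    lambdas = np.geomspace(lam_max, lam_max * settings.lambda_min_ratio,
                           settings.n_lambda)
    betas, intercepts, logliks, n_valid = logistic_lasso_path(X, y, lambdas)
    if n_valid == 0:
        raise RuntimeError(f"node {node!r}: no penalty converged")
    betas = betas[:n_valid]
    betas[np.abs(betas) < _COEF_SNAP] = 0.0
    return {
        "node": node,
        "predictors": predictors,
        "lambdas": lambdas[:n_valid],
        "coefs": betas,
        "intercepts": intercepts[:n_valid],
        "logliks": logliks[:n_valid],
        "truncated": n_valid < len(lambdas),
    }


class MixedGraphicalModel:
    """Mixed binary/continuous network model.

    Parameters
    ----------
    data : ItemMatrix
        Binary and continuous columns with metadata, or
    families : dict, optional
        ``column -> {"binary", "continuous"}``; required when ``data`` is a
        plain DataFrame.
    """

    def __init__(self, data, families: dict[str, str] | None = None,
                 settings: EstimationSettings | None = None,
                 **settings_kwargs):
        if settings is not None and settings_kwargs:
            raise ValueError("pass either settings or keyword overrides")
        self.settings = settings or EstimationSettings(**settings_kwargs)
        if isinstance(data, ItemMatrix):
            self.data = data.values
            self.families = data.var_types
        else:
            self.data = pd.DataFrame(data)
            if families is None:
                raise ValueError("families required when data is a DataFrame")
            self.families = dict(families)
        missing = set(self.data.columns) - set(self.families)
        if missing:
            raise ValueError(f"no family assigned to node(s): {sorted(missing)}")
        for c in self.data.columns:
            if self.families[c] == "binary":
                if not np.isin(self.data[c].to_numpy(), (0, 1)).all():
                    raise ValueError(f"binary node {c!r} is not 0/1")
        self.node_names = list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def fit(self) -> "MGMResults":
        values = self.data.copy()
        skipped: list[str] = []
        # standardize continuous columns in place
        for c in self.node_names:
            if self.families[c] == "continuous":
                col = values[c].to_numpy(dtype=float)
                sd = col.std()
                if sd == 0:
                    raise ValueError(f"node {c!r} is constant")
                values[c] = (col - col.mean()) / sd

        selections: dict = {}
        for name in self.node_names:
            col = values[name].to_numpy()
            if col.min() == col.max():
                if self.settings.on_constant == "skip":
                    selections[name] = None
                    skipped.append(name)
                    continue
                raise ValueError(f"node {name!r} is constant")
            if self.families[name] == "binary":
                path = _logistic_path(values, name, self.settings)
            else:
                path = _gaussian_path(values, name, self.settings)
            selections[name] = select_by_ebic(path, self.n, self.settings.gamma)

        net = assemble_network(
            selections, self.settings, self.node_names,
            extra_settings={"engine": "mgm", "n": self.n,
                            "skipped_nodes": skipped},
        )
        return MGMResults(self, net, selections)


class MGMResults(EstimatedNetwork):
    """Fitted mixed graphical model."""

    def __init__(self, model: MixedGraphicalModel, net: EstimatedNetwork,
                 selections):
        super().__init__(net.weights, net.thresholds, net.node_names,
                         net.settings, families=model.families)
        self.model = model
        self.selections = selections

    def centrality(self, communities: dict[str, str] | None = None):
        from .centrality import compute_centrality
        return compute_centrality(self, communities=communities)

    def summary(self) -> str:
        k_bin = sum(1 for f in self.families.values() if f == "binary")
        lines = [
            "Mixed graphical model (nodewise EBIC lasso)",
            "=" * 43,
            f"nodes:            {self.p} ({k_bin} binary, "
            f"{self.p - k_bin} continuous)",
            f"observations:     {self.settings.get('n', self.model.n)}",
            f"gamma:            {self.settings.get('gamma')}",
            f"rule:             {self.settings.get('rule')}",
            f"possible edges:   {self.n_possible_edges}",
            f"nonzero edges:    {self.n_edges} "
            f"({100 * self.n_edges / self.n_possible_edges:.0f}%)",
            f"mean |weight|:    {self.mean_abs_weight():.2f}",
        ]
        return "\n".join(lines)


def fit_mgm(items: ItemMatrix, settings: EstimationSettings | None = None,
            **kwargs) -> MGMResults:
    """Convenience wrapper: fit a mixed graphical model to an ItemMatrix."""
    return MixedGraphicalModel(items, settings=settings, **kwargs).fit()
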