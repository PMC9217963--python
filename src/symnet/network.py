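"""Estimated-network container shared by the Ising and mixed estimators."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


@dataclass
class EstimationSettings:
    """Settings for nodewise regularized estimation.

    Attributes
    ----------
    gamma : float
        EBIC hyperparameter (>= 0); 0 reduces to the BIC, larger values
        select sparser networks.
    n_lambda : int
        Length of the per-node penalty path.
    lambda_min_ratio : float
        Smallest penalty as a fraction of the per-node lambda_max.
    rule : {"AND", "OR"}
        Edge symmetrization: AND keeps an edge only when both directed
        regressions select it; OR keeps it when either does.
    aggregation : {"mean"}
        How the two directed coefficients combine into one edge weight
        (OR substitutes zero for a missing coefficient).
    on_constant : {"error", "skip"}
        Whether a constant node column aborts estimation or is skipped
        with all its edges recorded absent (used in bootstrap resamples
        where rare items can vanish).
    """

    gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"
    aggregation: str = "mean"
    on_constant: str = "error"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        self.rule = self.rule.upper()
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.aggregation != "mean":
            raise ValueError("only 'mean' aggregation is supported")
        if self.on_constant not in ("error", "skip"):
            raise ValueError("on_constant must be 'error' or 'skip'")

    def to_dict(self) -> dict:
        return asdict(self)


class EstimatedNetwork:
    """A symmetric weighted network with node thresholds and settings.

    Attributes
    ----------
    weights : (p, p) ndarray
        Symmetric edge-weight matrix, zero diagonal.
    thresholds : (p,) ndarray
        Selected-model intercepts per node.
    node_names : list of str
    settings : dict
        Estimation settings and metadata (gamma, rule, engine, n, ...).
    families : dict or None
        ``node -> {"binary", "continuous"}`` for mixed networks.
    """

    def __init__(self, weights, thresholds, node_names, settings=None,
                 families=None):
        weights = np.asarray(weights, dtype=float)
        thresholds = np.asarray(thresholds, dtype=float)
        p = weights.shape[0]
        if weights.shape != (p, p):
            raise ValueError("weights must be square")
        if not np.allclose(weights, weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if thresholds.shape != (p,):
            raise ValueError("thresholds length must match weights")
        if len(node_names) != p:
            raise ValueError("node_names length must match weights")
        weights = 0.5 * (weights + weights.T)
        np.fill_diagonal(weights, 0.0)
        self.weights = weights
        self.thresholds = thresholds
        self.node_names = list(node_names)
        self.settings = dict(settings or {})
        self.families = dict(families) if families else None

    # -- structure -----------------------------------------------------------

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    def edge_list(self, tol: float = 0.0) -> pd.DataFrame:
        """Nonzero edges as a tidy frame (node_a, node_b, weight), i < j."""
        iu = np.triu_indices(self.p, k=1)
        w = self.weights[iu]
        mask = np.abs(w) > tol
        return pd.DataFrame({
            "node_a": [self.node_names[i] for i in iu[0][mask]],
            "node_b": [self.node_names[j] for j in iu[1][mask]],
            "weight": w[mask],
        })

    def edge_set(self, tol: float = 0.0) -> set[tuple[str, str]]:
        df = self.edge_list(tol)
        return set(zip(df["node_a"], df["node_b"]))

    @property
    def n_edges(self) -> int:
        return len(self.edge_list())

    def mean_abs_weight(self) -> float:
        """Mean absolute weight over nonzero edges (0 for an empty network)."""
        w = self.edge_list()["weight"].to_numpy()
        return float(np.mean(np.abs(w))) if len(w) else 0.0

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_names,
                            columns=self.node_names)

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "node_names": self.node_names,
            "weights": self.weights.tolist(),
            "thresholds": self.thresholds.tolist(),
            "settings": self.settings,
        }
        if self.families is not None:
            d["families"] = self.families
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EstimatedNetwork":
        return cls(np.array(d["weights"]), np.array(d["thresholds"]),
                   d["node_names"], d.get("settings"), d.get("families"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EstimatedNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self):  # pragma: no cover
        return (f"{type(self).__name__}(p={self.p}, edges={self.n_edges}"
                f"/{self.n_possible_edges})")
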