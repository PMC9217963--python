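"""Bootstrap diagnostics: case-dropping centrality stability and
nonparametric edge-weight accuracy.

Two complementary checks of how much an estimated network can be trusted:

* **Case-dropping bootstrap / CS-coefficient.** Re-estimate the network on
  subsamples with an increasing proportion of participants dropped and
  correlate (Spearman) each subsample's centrality ordering with the
  full-sample one.  The correlation-stability coefficient CS(cor = 0.7) is
  the largest drop proportion at which at least 95% of subsamples still
  correlate >= 0.7 with the full sample; CS >= 0.5 is conventionally read
  as stable, CS >= 0.25 as minimally acceptable.

* **Edge bootstrap.** Re-estimate on resamples drawn with replacement;
  report percentile 95% confidence intervals per edge and the retention
  fraction (how often each edge is nonzero).  Downstream reporting keeps
  only edges present in at least 70% of bootstraps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ItemMatrix
from .ising import IsingModel
from .network import EstimatedNetwork, EstimationSettings

__all__ = ["case_drop_bootstrap", "cs_coefficient", "edge_bootstrap",
           "retain_edges", "StabilitySummary", "CaseDropResult"]

logger = logging.getLogger("symnet")

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
DEFAULT_INDICES = ("strength", "closeness", "betweenness", "ei1", "ei2")


def _default_fit(settings: EstimationSettings | None):
    base = settings or EstimationSettings()
    # constant columns are expected in resamples of rare items: skip them
    boot = EstimationSettings(**{**base.to_dict(), "on_constant": "skip"})

    def fit(data: ItemMatrix) -> EstimatedNetwork:
        return IsingModel(data, settings=boot).fit()

    return fit


def cs_coefficient(correlations: dict[float, np.ndarray], cor: float = 0.7,
                   prop: float = 0.95) -> float:
    """CS-coefficient from per-drop-proportion correlation samples.

    The largest drop proportion d such that at least ``prop`` of the
    correlations at every drop <= d are >= ``cor``; 0.0 when even the
    smallest drop fails.
    """
    cs = 0.0
    for d in sorted(correlations):
        vals = np.asarray(correlations[d], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0 or np.mean(vals >= cor) < prop:
            break
        cs = d
    return cs


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap output.

    ``cs`` maps each centrality index to its CS(cor = 0.7);
    ``correlations`` maps index -> {drop proportion -> correlation samples};
    ``n_degenerate`` counts subsamples excluded because the subsample
    centrality was constant (correlation undefined).
    """

    cs: dict[str, float]
    correlations: dict[str, dict[float, np.ndarray]]
    n_degenerate: int
    B: int
    drops: tuple


def case_drop_bootstrap(
    items: ItemMatrix,
    estimator: EstimationSettings | None = None,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    drops: tuple = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    communities: dict[str, str] | None = None,
    fit=None,
) -> CaseDropResult:
    """Case-dropping bootstrap of centrality indices.

    Parameters
    ----------
    items : ItemMatrix
    estimator : EstimationSettings, optional
        Ising eLasso settings (ignored when ``fit`` is given).
    indices : tuple of str
        Centrality columns to track; include ``bei1``/``bei2`` only with
        ``communities``.
    drops : tuple of float in (0, 1)
        Grid of drop proportions.
    B : int
        Subsamples per drop proportion.
    fit : callable, optional
        ``ItemMatrix -> EstimatedNetwork``; overrides ``estimator``.
    """
    from .centrality import compute_centrality

    if B < 1:
        raise ValueError("B must be >= 1")
    if any(not (0 < d < 1) for d in drops):
        raise ValueError("drop proportions must lie in (0, 1)")
    fit = fit or _default_fit(estimator)
    full = compute_centrality(fit(items), communities=communities)
    missing = [ix for ix in indices if ix not in full.columns]
    if missing:
        raise ValueError(f"unknown centrality index(es): {missing}")

    n = items.n
    master = np.random.SeedSequence(seed)
    correlations: dict[str, dict[float, list]] = {
        ix: {float(d): [] for d in drops} for ix in indices
    }
    n_degenerate = 0
    for d, child in zip(drops, master.spawn(len(drops))):
        m = max(3, int(round((1.0 - d) * n)))
        for ss in child.spawn(B):
            rng = np.random.default_rng(ss)
            idx = rng.choice(n, size=m, replace=False)
            try:
                sub = compute_centrality(fit(items.take_rows(idx)),
                                         communities=communities)
            except Exception as exc:  # estimator failure in a subsample
                logger.warning("case-drop subsample failed (drop=%s): %s", d, exc)
                n_degenerate += 1
                continue
            for ix in indices:
                a = full[ix].to_numpy()
                b = sub[ix].to_numpy()
                if np.all(b == b[0]) or np.all(a == a[0]):
                    n_degenerate += 1
                    continue
                rho = stats.spearmanr(a, b).statistic
                correlations[ix][float(d)].append(rho)
    corr_arrays = {
        ix: {d: np.asarray(v) for d, v in per.items()}
        for ix, per in correlations.items()
    }
    cs = {ix: cs_coefficient(corr_arrays[ix]) for ix in indices}
    if n_degenerate:
        logger.info("case-drop bootstrap: %d degenerate/failed subsamples "
                    "excluded", n_degenerate)
    return CaseDropResult(cs=cs, correlations=corr_arrays,
                          n_degenerate=n_degenerate, B=B, drops=tuple(drops))


def edge_bootstrap(
    items: ItemMatrix,
    estimator: EstimationSettings | None = None,
    B: int = 1000,
    seed: int = 0,
    fit=None,
) -> pd.DataFrame:
    """Nonparametric bootstrap of edge weights.

    B resamples with replacement, full re-estimation on each.  Returns a
    frame over all node pairs (i < j) with the percentile 95% CI
    (``ci_lo``, ``ci_hi``), the bootstrap mean weight, and ``retention``
    (fraction of successful resamples in which the edge is nonzero).
    Resamples where estimation fails are skipped and logged, with the
    denominator adjusted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fit = fit or _default_fit(estimator)
    names = items.node_names
    p = len(names)
    iu = np.triu_indices(p, k=1)
    draws = []
    n = items.n
    master = np.random.SeedSequence(seed)
    n_failed = 0
    for ss in master.spawn(B):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        try:
            net = fit(items.take_rows(idx))
        except Exception as exc:
            n_failed += 1
            logger.warning("edge bootstrap resample failed: %s", exc)
            continue
        if net.node_names != names:
            raise ValueError("fit returned a network over a different node set")
        draws.append(net.weights[iu])
    if not draws:
        raise RuntimeError("all bootstrap resamples failed")
    if n_failed:
        logger.info("edge bootstrap: %d/%d resamples failed and were skipped",
                    n_failed, B)
    W = np.vstack(draws)  # B_ok x n_pairs
    lo, hi = np.percentile(W, [2.5, 97.5], axis=0)
    out = pd.DataFrame({
        "node_a": [names[i] for i in iu[0]],
        "node_b": [names[j] for j in iu[1]],
        "ci_lo": lo,
        "ci_hi": hi,
        "boot_mean": W.mean(axis=0),
        "retention": (W != 0).mean(axis=0),
    })
    out.attrs["B"] = B
    out.attrs["n_failed"] = n_failed
    return out


def retain_edges(net: EstimatedNetwork, retention: pd.DataFrame,
                 threshold: float = 0.70) -> EstimatedNetwork:
    """Zero out edges retained in fewer than ``threshold`` of bootstraps.

    ``retention`` is the frame from :func:`edge_bootstrap` (columns
    ``node_a``, ``node_b``, ``retention``).  Edges with retention >=
    threshold are unchanged; the operation is idempotent.
    """
    frac = {(r.node_a, r.node_b): r.retention
            for r in retention.itertuples(index=False)}
    missing = [e for e in net.edge_set() if e not in frac]
    if missing:
        raise ValueError(f"retention not defined for edge(s): {missing}")
    W = net.weights.copy()
    names = net.node_names
    pos = {c: i for i, c in enumerate(names)}
    for (a, b), f in frac.items():
        if f < threshold:
            W[pos[a], pos[b]] = W[pos[b], pos[a]] = 0.0
    settings = dict(net.settings)
    settings["retention_threshold"] = threshold
    return EstimatedNetwork(W, net.thresholds, names, settings, net.families)


@dataclass
class StabilitySummary:
    """Combined stability diagnostics for one estimated network."""

    cs: dict[str, float]
    edge_ci: pd.DataFrame
    B_case: int
    B_edge: int

    def to_dict(self) -> dict:
        return {
            "cs": self.cs,
            "B_case": self.B_case,
            "B_edge": self.B_edge,
            "edges": self.edge_ci.to_dict(orient="records"),
        }
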