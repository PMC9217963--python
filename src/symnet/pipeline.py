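"""End-to-end analysis orchestration.

A *run* takes a prepared item matrix through redundancy screening, network
estimation (Ising eLasso or MGM), centrality and bridge identification, and
(optionally) bootstrap stability with the 70%-retention rule, writing all
artifacts plus a markdown report.  Two standard steps mirror the incremental
design of the analysis: step 1 is the 14-node symptom/impairment network;
step 2 adds the six risk-factor nodes (20 nodes).  Sensitivity utilities
down-sample the cohort on psychosis-symptom presence and diff two networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import BridgeResult, compute_centrality, select_bridges
from .data import ItemMatrix
from .ising import IsingModel
from .io import write_network
from .mgm import MixedGraphicalModel
from .network import EstimatedNetwork, EstimationSettings
from .preprocess import goldbricker
from .stability import (StabilitySummary, case_drop_bootstrap, edge_bootstrap,
                        retain_edges)

__all__ = ["RunConfig", "RunResult", "run_step", "downsample_cohort",
           "compare_networks", "NetworkDiff"]

logger = logging.getLogger("symnet")


@dataclass
class RunConfig:
    """Configuration for one network-analysis run.

    Attributes
    ----------
    step : str
        Label for the run (e.g. ``step1``, ``step2``).
    nodes : list of str or None
        Columns to analyze (None = all columns of the item matrix).
    engine : {"ising", "mgm"}
    estimator : EstimationSettings
    bridge_fraction : float
        Top fraction of nodes (by two-step bridge EI) called bridges.
    B_case, B_edge : int
        Bootstrap counts for the case-dropping and edge bootstraps;
        0 skips that diagnostic.
    retention_threshold : float
        Minimum bootstrap retention for a reported edge.
    allow_redundant : bool
        Continue despite a non-empty redundancy screen.
    seed : int
    out_dir : str or None
        Where to write artifacts (None = in-memory only).
    """

    step: str = "step1"
    nodes: list[str] | None = None
    engine: str = "ising"
    estimator: EstimationSettings = field(default_factory=EstimationSettings)
    bridge_fraction: float = 0.25
    B_case: int = 0
    B_edge: int = 0
    retention_threshold: float = 0.70
    allow_redundant: bool = False
    goldbricker_cor_min: float = 0.5
    goldbricker_threshold: float = 0.25
    goldbricker_alpha: float = 0.01
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.engine not in ("ising", "mgm"):
            raise ValueError("engine must be 'ising' or 'mgm'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "estimator" in d and isinstance(d["estimator"], dict):
            d["estimator"] = EstimationSettings(**d["estimator"])
        return cls(**d)


class RedundancyError(RuntimeError):
    """Raised when the goldbricker screen flags node pairs."""

    def __init__(self, report):
        self.report = report
        pairs = [(a, b) for a, b, *_ in report.flagged_pairs]
        super().__init__(
            f"redundant node pair(s) flagged: {pairs}; merge or drop one of "
            "each pair, or rerun with allow_redundant"
        )


@dataclass
class RunResult:
    """All artifacts from one pipeline run."""

    config: RunConfig
    network: EstimatedNetwork
    reported_network: EstimatedNetwork
    centrality: pd.DataFrame
    bridges: BridgeResult
    redundancy: object
    stability: StabilitySummary | None
    report: str


def _report_markdown(cfg: RunConfig, net: EstimatedNetwork,
                     reported: EstimatedNetwork, bridges: BridgeResult,
                     stability: StabilitySummary | None) -> str:
    p = net.p
    possible = net.n_possible_edges
    n_nonzero = net.n_edges
    pct = round(100.0 * n_nonzero / possible) if possible else 0
    lines = [
        f"# Network run report: {cfg.step}",
        "",
        f"- engine: {cfg.engine} (gamma={cfg.estimator.gamma}, "
        f"rule={cfg.estimator.rule})",
        f"- seed: {cfg.seed}",
        f"- observations: {net.settings.get('n', 'NA')}",
        f"- nodes: {p}",
        f"- possible edges: {possible}",
        f"- nonzero edges: {n_nonzero} ({pct}%)",
        f"- mean |nonzero edge weight|: {net.mean_abs_weight():.2f}",
        f"- bridge nodes (top {int(round(cfg.bridge_fraction * 100))}% "
        f"two-step bridge EI): {', '.join(bridges.selected)}",
    ]
    if stability is not None:
        cs = ", ".join(f"{k}={v:.2f}" for k, v in stability.cs.items())
        lines += [
            f"- CS-coefficients (cor=0.7): {cs}",
            f"- edges retained at {cfg.retention_threshold:.0%} bootstrap "
            f"retention: {reported.n_edges}/{n_nonzero}",
        ]
    return "\n".join(lines) + "\n"


def run_step(cfg: RunConfig, items: ItemMatrix) -> RunResult:
    """Execute one full analysis step on an item matrix.

    Order: redundancy screen -> estimation -> centrality and bridges ->
    bootstrap stability (if configured) -> retention filtering -> report.
    The redundancy screen halting behavior follows ``cfg.allow_redundant``.
    """
    data = items.subset(cfg.nodes) if cfg.nodes is not None else items
    communities = data.communities
    logger.info("run %s: n=%d, p=%d, engine=%s, seed=%d",
                cfg.step, data.n, data.p, cfg.engine, cfg.seed)

    redundancy = goldbricker(data, cor_min=cfg.goldbricker_cor_min,
                             threshold=cfg.goldbricker_threshold,
                             alpha=cfg.goldbricker_alpha)
    if not redundancy.is_empty:
        logger.warning("redundancy screen flagged %d pair(s)",
                       len(redundancy.flagged_pairs))
        if not cfg.allow_redundant:
            raise RedundancyError(redundancy)

    if cfg.engine == "ising":
        model = IsingModel(data, settings=cfg.estimator)
    else:
        model = MixedGraphicalModel(data, settings=cfg.estimator)
    net = model.fit()
    logger.info("run %s: %d/%d nonzero edges", cfg.step, net.n_edges,
                net.n_possible_edges)

    centrality = compute_centrality(net, communities=communities)
    bridges = select_bridges(centrality["bei2"], fraction=cfg.bridge_fraction)

    stability = None
    reported = net
    if cfg.B_case > 0 or cfg.B_edge > 0:
        cs = {}
        B_case = 0
        if cfg.B_case > 0:
            cd = case_drop_bootstrap(data, estimator=cfg.estimator,
                                     B=cfg.B_case, seed=cfg.seed + 1,
                                     communities=communities)
            cs, B_case = cd.cs, cd.B
        if cfg.B_edge > 0:
            edge_ci = edge_bootstrap(data, estimator=cfg.estimator,
                                     B=cfg.B_edge, seed=cfg.seed + 2)
            reported = retain_edges(net, edge_ci,
                                    threshold=cfg.retention_threshold)
        else:
            edge_ci = pd.DataFrame()
        stability = StabilitySummary(cs=cs, edge_ci=edge_ci,
                                     B_case=B_case, B_edge=cfg.B_edge)

    report = _report_markdown(cfg, net, reported, bridges, stability)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_network(net, out / f"{cfg.step}.net")
        if reported is not net:
            write_network(reported, out / f"{cfg.step}.net.retained")
        centrality.to_csv(out / f"{cfg.step}.centrality.tsv", sep="\t")
        import json
        (out / f"{cfg.step}.bridges.json").write_text(
            json.dumps(bridges.to_dict(), indent=1))
        (out / f"{cfg.step}.redundancy.json").write_text(
            json.dumps(redundancy.to_dict(), indent=1))
        if stability is not None:
            (out / f"{cfg.step}.stability.json").write_text(
                json.dumps(stability.to_dict(), indent=1))
        (out / f"{cfg.step}.report.md").write_text(report)

    return RunResult(config=cfg, network=net, reported_network=reported,
                     centrality=centrality, bridges=bridges,
                     redundancy=redundancy, stability=stability,
                     report=report)


def downsample_cohort(items: ItemMatrix, positive_nodes: list[str],
                      seed: int = 0) -> ItemMatrix:
    """Balance a rare-outcome cohort for a sensitivity re-analysis.

    Keeps every participant endorsing at least one of ``positive_nodes``
    (e.g. any lifetime psychosis symptom) plus an equal-sized simple random
    sample (without replacement) of never-endorsing participants; the
    result has exactly twice as many rows as there are positives.
    """
    unknown = [c for c in positive_nodes if c not in items.node_names]
    if unknown:
        raise KeyError(f"unknown node(s): {unknown}")
    pos_mask = (items.values[positive_nodes].to_numpy() == 1).any(axis=1)
    pos_idx = np.nonzero(pos_mask)[0]
    neg_idx = np.nonzero(~pos_mask)[0]
    if len(pos_idx) == 0:
        raise ValueError("no participants endorse any positive node")
    if len(neg_idx) < len(pos_idx):
        raise ValueError(
            f"cannot match {len(pos_idx)} positives: only {len(neg_idx)} "
            "negatives available"
        )
    rng = np.random.default_rng(seed)
    sampled_neg = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    keep = np.sort(np.concatenate([pos_idx, sampled_neg]))
    logger.info("downsample: %d positives + %d matched negatives = %d rows",
                len(pos_idx), len(pos_idx), 2 * len(pos_idx))
    return items.take_rows(keep)


@dataclass
class NetworkDiff:
    """Structural comparison of two networks over the same node set."""

    only_in_a: set[tuple[str, str]]
    only_in_b: set[tuple[str, str]]
    weight_deltas: pd.DataFrame
    bridges_a: list[str] | None = None
    bridges_b: list[str] | None = None

    @property
    def is_empty(self) -> bool:
        return (not self.only_in_a and not self.only_in_b
                and bool(np.all(self.weight_deltas["delta"] == 0)))

    @property
    def bridge_agreement(self) -> bool | None:
        if self.bridges_a is None or self.bridges_b is None:
            return None
        return set(self.bridges_a) == set(self.bridges_b)


def compare_networks(a: EstimatedNetwork, b: EstimatedNetwork,
                     communities: dict[str, str] | None = None,
                     bridge_fraction: float = 0.25) -> NetworkDiff:
    """Diff two networks: edge-set differences, weight deltas, and (when
    communities are given) agreement of their bridge-node sets."""
    if a.node_names != b.node_names:
        raise ValueError("networks are defined over different node sets")
    ea, eb = a.edge_set(), b.edge_set()
    iu = np.triu_indices(a.p, k=1)
    deltas = pd.DataFrame({
        "node_a": [a.node_names[i] for i in iu[0]],
        "node_b": [a.node_names[j] for j in iu[1]],
        "weight_a": a.weights[iu],
        "weight_b": b.weights[iu],
        "delta": b.weights[iu] - a.weights[iu],
    })
    bridges_a = bridges_b = None
    if communities is not None:
        ca = compute_centrality(a, communities=communities)
        cb = compute_centrality(b, communities=communities)
        bridges_a = select_bridges(ca["bei2"], bridge_fraction).selected
        bridges_b = select_bridges(cb["bei2"], bridge_fraction).selected
    return NetworkDiff(only_in_a=ea - eb, only_in_b=eb - ea,
                       weight_deltas=deltas,
                       bridges_a=bridges_a, bridges_b=bridges_b)
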