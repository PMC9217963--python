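"""Synthetic cohort generation from community-structured Ising models.

The analysis pipeline operates on binary lifetime-symptom items whose joint
distribution is modelled as a pairwise Markov random field (Ising model)
over states x in {0,1}^p:

    P(x) propto exp( sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j )

with node thresholds ``tau`` and symmetric couplings ``omega``.  The {0,1}
parameterization is used (rather than {-1,+1}) so couplings live on the same
conditional-logit scale as the nodewise logistic-regression estimator: the
full conditional of node i is

    P(x_i = 1 | x_-i) = logistic( tau_i + sum_j omega_ij x_j ).

This module provides

* an exact sampler (full state enumeration, p <= 20),
* a vectorized Gibbs sampler for larger graphs,
* threshold calibration so model marginals match target endorsement rates,
* generation of community-structured graphs with designated bridge edges,
* questionnaire skip-logic (follow-up items gated on core items),
* continuous risk-factor covariates linearly coupled to symptoms,
* a ready-made 20-node cohort ("ukb-like") emulating a large population
  mental-health questionnaire: 9 depression + 5 psychosis binary items with
  realistic endorsement rates (psychosis items are rare), two planted
  bridge edges, and six risk-factor covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import ItemMatrix, NodeMeta

MAX_EXACT_P = 20

__all__ = [
    "IsingGraph",
    "SimulationConfig",
    "SkipRule",
    "generate_structured_graph",
    "sample_ising_exact",
    "sample_ising_gibbs",
    "calibrate_thresholds",
    "exact_marginals",
    "exact_state_probabilities",
    "apply_skip_logic",
    "generate_mixed_covariates",
    "ukb_like_cohort",
    "UKB_LIKE_MARGINALS",
]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class IsingGraph:
    """Ising model parameters: symmetric couplings and node thresholds.

    Parameters
    ----------
    omega : (p, p) ndarray
        Symmetric coupling matrix with zero diagonal.
    tau : (p,) ndarray
        Node thresholds (log-odds of endorsement for an isolated node).
    node_names : list of str, optional
        Node labels; defaults to ``X1..Xp``.
    """

    omega: np.ndarray
    tau: np.ndarray
    node_names: list[str] | None = None

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        p = self.omega.shape[0]
        if self.omega.shape != (p, p):
            raise ValueError("omega must be square")
        if self.tau.shape != (p,):
            raise ValueError("tau length must match omega")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(self.omega), 0.0):
            raise ValueError("omega must have zero diagonal")
        if not (np.isfinite(self.omega).all() and np.isfinite(self.tau).all()):
            raise ValueError("omega and tau must be finite")
        self.omega = 0.5 * (self.omega + self.omega.T)
        np.fill_diagonal(self.omega, 0.0)
        if self.node_names is None:
            self.node_names = [f"X{i + 1}" for i in range(p)]
        if len(self.node_names) != p:
            raise ValueError("node_names length must match omega")

    @property
    def p(self) -> int:
        return self.omega.shape[0]

    def edge_set(self, tol: float = 0.0) -> set[tuple[int, int]]:
        """Index pairs (i < j) with |omega_ij| > tol."""
        iu = np.triu_indices(self.p, k=1)
        mask = np.abs(self.omega[iu]) > tol
        return set(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


# ---------------------------------------------------------------------------
# exact distribution (p <= 20)
# ---------------------------------------------------------------------------

def _state_table(p: int) -> np.ndarray:
    """All 2^p binary states as a (2^p, p) float32 array (bit i -> column i)."""
    ints = np.arange(2 ** p, dtype=np.uint32)
    return ((ints[:, None] >> np.arange(p, dtype=np.uint32)) & 1).astype(np.float32)


def _check_exact_p(p: int):
    if p > MAX_EXACT_P:
        raise ValueError(
            f"exact enumeration supports p <= {MAX_EXACT_P} (got p={p}); "
            "use sample_ising_gibbs for larger graphs"
        )


def exact_state_probabilities(graph: IsingGraph) -> np.ndarray:
    """Probability of every state in bit order (state s has bit i = x_i)."""
    _check_exact_p(graph.p)
    S = _state_table(graph.p)
    # interaction term 0.5 * x' omega x equals sum_{i<j} omega_ij x_i x_j
    logp = (S @ graph.tau.astype(np.float32)).astype(np.float64)
    logp += 0.5 * np.einsum("ij,ij->i", S @ graph.omega.astype(np.float32), S,
                            dtype=np.float64)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return prob


def exact_marginals(graph: IsingGraph) -> np.ndarray:
    """Exact endorsement probability P(x_i = 1) for every node (p <= 20)."""
    prob = exact_state_probabilities(graph)
    S = _state_table(graph.p)
    return (prob.astype(np.float32) @ S).astype(np.float64)


def sample_ising_exact(graph: IsingGraph, n: int, seed: int) -> ItemMatrix:
    """Draw n i.i.d. samples from the exact Ising distribution (p <= 20).

    The full 2^p state space is enumerated, so samples are exact draws,
    not Markov-chain output.
    """
    _check_exact_p(graph.p)
    if n < 1:
        raise ValueError("n must be >= 1")
    prob = exact_state_probabilities(graph)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(prob)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(n), side="right").astype(np.uint32)
    bits = ((idx[:, None] >> np.arange(graph.p, dtype=np.uint32)) & 1).astype(np.int8)
    values = pd.DataFrame(bits, columns=graph.node_names)
    return ItemMatrix(values, [NodeMeta(name=c) for c in graph.node_names])


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def sample_ising_gibbs(
    graph: IsingGraph,
    n: int,
    burn_in: int = 500,
    thin: int = 10,
    seed: int = 0,
    init: str = "random",
) -> ItemMatrix:
    """Draw n approximate samples via Gibbs sampling.

    ``n`` independent chains are run in parallel (vectorized over chains) for
    ``burn_in + thin`` full sweeps; the final state of each chain is one
    sample.  Chains are independent, so samples are i.i.d. with respect to
    each other and approximate with respect to the stationary distribution
    only through the burn-in length.  Each site update draws

        x_i ~ Bernoulli( logistic(tau_i + sum_j omega_ij x_j) ).

    Parameters
    ----------
    init : {"random", "zeros", "ones"}
        Chain initialization; "random" draws each entry Bernoulli(1/2).
    """
    if burn_in < 1 or thin < 1:
        raise ValueError("burn_in and thin must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = graph.p
    if init == "random":
        X = (rng.random((n, p)) < 0.5).astype(np.float64)
    elif init == "zeros":
        X = np.zeros((n, p))
    elif init == "ones":
        X = np.ones((n, p))
    else:
        raise ValueError(f"unknown init {init!r}")
    omega, tau = graph.omega, graph.tau
    for _ in range(burn_in + thin):
        for i in range(p):
            pr = expit(tau[i] + X @ omega[:, i])
            X[:, i] = rng.random(n) < pr
    values = pd.DataFrame(X.astype(np.int8), columns=graph.node_names)
    return ItemMatrix(values, [NodeMeta(name=c) for c in graph.node_names])


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    graph: IsingGraph,
    target_marginals: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 2000,
    damping: float = 0.5,
    skip_rules: "list[SkipRule] | None" = None,
) -> IsingGraph:
    """Adjust thresholds so exact model marginals match target rates.

    Iterative moment matching: each iteration computes exact marginals
    m (p <= 20) and updates ``tau_i += damping * (logit(t_i) - logit(m_i))``.
    With zero couplings this converges in one step to ``tau = logit(t)``.

    Parameters
    ----------
    target_marginals : array-like in (0, 1)
        Desired endorsement probability per node.
    tol : float
        Convergence criterion on max |m - t|; the default is well inside
        the 0.01 agreement the generator guarantees.
    skip_rules : list of SkipRule, optional
        When given, targets are matched on the *post-gating* endorsement
        rates (questionnaire frequencies are observed after skip logic, so
        a gated item's rate is P(item and at least one gate endorsed)).
        Targets must then be achievable: a gated item's target cannot
        exceed the probability that its gates fire.

    Raises
    ------
    RuntimeError
        If not converged within ``max_iter``, reporting the worst node.
    """
    _check_exact_p(graph.p)
    t = np.asarray(target_marginals, dtype=float)
    if t.shape != (graph.p,):
        raise ValueError("target_marginals length must match graph")
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("target marginals must lie strictly in (0, 1)")

    # precompute state table and the tau-independent interaction term once
    S = _state_table(graph.p)
    inter = 0.5 * np.einsum("ij,ij->i", S @ graph.omega.astype(np.float32), S,
                            dtype=np.float64)
    if skip_rules:
        # post-gating value of every node in every state
        S_eff = _apply_rules_to_array(S.copy(), skip_rules, graph.node_names)
    else:
        S_eff = S
    tau = graph.tau.copy()
    target_logit = logit(t)
    for _ in range(max_iter):
        lp = inter + (S @ tau.astype(np.float32)).astype(np.float64)
        lp -= lp.max()
        prob = np.exp(lp)
        prob /= prob.sum()
        m = (prob.astype(np.float32) @ S_eff).astype(np.float64)
        if np.max(np.abs(m - t)) < tol:
            return IsingGraph(graph.omega.copy(), tau, list(graph.node_names))
        m = np.clip(m, 1e-12, 1 - 1e-12)
        tau += damping * (target_logit - logit(m))
    worst = int(np.argmax(np.abs(m - t)))
    raise RuntimeError(
        f"threshold calibration did not converge in {max_iter} iterations; "
        f"worst node {graph.node_names[worst]!r}: marginal {m[worst]:.4f} "
        f"vs target {t[worst]:.4f}"
    )


# ---------------------------------------------------------------------------
# structured graph generation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Configuration for community-structured Ising graph generation.

    Attributes
    ----------
    p : int
        Node count.
    communities : dict
        ``node name -> community label``; iteration order fixes node order.
    within_weight_range : (float, float)
        Couplings within a community are drawn uniformly from this interval.
    bridge_edges : list of (str, str, float)
        Cross-community couplings; the only nonzero entries between
        communities.  Pairs must span two distinct communities.
    within_density : float
        Probability that any given within-community pair receives an edge.
    target_marginals : dict or None
        ``node name -> endorsement probability`` in (0, 1); when given,
        thresholds are calibrated to these targets (p <= 20), otherwise
        thresholds start at 0.
    n : int
        Default sample size when the config is used to generate a cohort.
    seed : int
        RNG seed for graph generation.
    """

    p: int
    communities: dict[str, str]
    within_weight_range: tuple[float, float] = (0.4, 1.2)
    bridge_edges: list[tuple[str, str, float]] = field(default_factory=list)
    within_density: float = 0.35
    target_marginals: dict[str, float] | None = None
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        if len(self.communities) != self.p:
            raise ValueError("communities must assign every one of the p nodes")
        if self.target_marginals is not None:
            bad = {k: v for k, v in self.target_marginals.items()
                   if not (0.0 < v < 1.0)}
            if bad:
                raise ValueError(f"target marginals outside (0,1): {bad}")
        names = list(self.communities)
        for a, b, _w in self.bridge_edges:
            if a not in names or b not in names:
                raise ValueError(f"bridge edge ({a},{b}) references unknown node")
            if self.communities[a] == self.communities[b]:
                raise ValueError(
                    f"bridge edge ({a},{b}) lies within community "
                    f"{self.communities[a]!r}; bridge edges must cross communities"
                )

    @property
    def node_names(self) -> list[str]:
        return list(self.communities)


def generate_structured_graph(cfg: SimulationConfig) -> IsingGraph:
    """Random Ising graph with community structure and designated bridges.

    Within-community pairs receive an edge with probability
    ``cfg.within_density`` and weight drawn uniformly from
    ``cfg.within_weight_range``; cross-community couplings are nonzero
    exactly at ``cfg.bridge_edges``.  Deterministic given ``cfg.seed``.
    Thresholds are calibrated to ``cfg.target_marginals`` when provided.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.node_names
    idx = {c: i for i, c in enumerate(names)}
    omega = np.zeros((cfg.p, cfg.p))
    lo, hi = cfg.within_weight_range
    for i in range(cfg.p):
        for j in range(i + 1, cfg.p):
            if cfg.communities[names[i]] == cfg.communities[names[j]]:
                if rng.random() < cfg.within_density:
                    w = rng.uniform(lo, hi)
                    omega[i, j] = omega[j, i] = w
    for a, b, w in cfg.bridge_edges:
        omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = w

    if cfg.target_marginals is not None:
        tau0 = np.array([logit(cfg.target_marginals[c]) for c in names])
        graph = IsingGraph(omega, tau0, names)
        graph = calibrate_thresholds(
            graph, np.array([cfg.target_marginals[c] for c in names])
        )
    else:
        graph = IsingGraph(omega, np.zeros(cfg.p), names)
    return graph


# ---------------------------------------------------------------------------
# skip logic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkipRule:
    """Questionnaire gating: ``gated`` items are asked only when at least one
    ``gate`` item is endorsed; otherwise they are recorded as absent (0)."""

    gates: tuple[str, ...]
    gated: tuple[str, ...]


def _rule_order(rules: list[SkipRule]) -> list[int]:
    """Topological order over rules (gates before their dependents);
    raises on cyclic gating."""
    gated_by_rule = {i: set(r.gated) for i, r in enumerate(rules)}
    order: list[int] = []
    remaining = set(range(len(rules)))
    while remaining:
        ready = [
            i for i in remaining
            if not any(set(rules[i].gates) & gated_by_rule[j]
                       for j in remaining if j != i)
        ]
        if not ready:
            raise ValueError("cyclic skip-logic gating detected")
        ready.sort()
        order.extend(ready)
        remaining -= set(ready)
    return order


def _apply_rules_to_array(arr: np.ndarray, rules: list[SkipRule],
                          node_names: list[str]) -> np.ndarray:
    """Apply gating to a rows x nodes array in place (absence coded 0)."""
    idx = {c: i for i, c in enumerate(node_names)}
    for r in rules:
        unknown = [c for c in (*r.gates, *r.gated) if c not in idx]
        if unknown:
            raise ValueError(f"skip rule references unknown column(s): {unknown}")
    for i in _rule_order(rules):
        r = rules[i]
        gate_off = (arr[:, [idx[g] for g in r.gates]] == 0).all(axis=1)
        for col in r.gated:
            arr[gate_off, idx[col]] = 0
    return arr


def apply_skip_logic(items: ItemMatrix, rules: list[SkipRule]) -> ItemMatrix:
    """Force gated items to 0 for participants endorsing none of the gates.

    Rules are applied in dependency order (a rule whose gates are themselves
    gated elsewhere is applied after the gating of its gates); cyclic gating
    raises ``ValueError``.
    """
    arr = items.values.to_numpy().copy()
    arr = _apply_rules_to_array(arr, rules, items.node_names)
    values = pd.DataFrame(arr, columns=items.node_names,
                          index=items.values.index)
    return ItemMatrix(values, items.meta)


# ---------------------------------------------------------------------------
# continuous covariates
# ---------------------------------------------------------------------------

def generate_mixed_covariates(
    items: ItemMatrix,
    coupling_spec: dict[str, dict[str, float]],
    noise_sd: float | dict[str, float] = 1.0,
    seed: int = 0,
    n_genetic_pcs: int = 5,
) -> ItemMatrix:
    """Append continuous risk-factor covariates coupled to named items.

    Each covariate is a linear combination of existing columns (binary items
    or previously generated covariates, in spec order) plus Gaussian noise:

        cov = sum_k coef_k * column_k + N(0, noise_sd^2).

    Additionally ``n_genetic_pcs`` independent standard-normal columns
    ``PC1..PCk`` are appended, mimicking genetic principal components used
    for population-stratification adjustment (independent of everything by
    construction).

    Parameters
    ----------
    coupling_spec : dict
        ``covariate name -> {column name: coefficient}``.  Covariates may
        reference covariates defined earlier in the dict.
    noise_sd : float or dict
        Noise standard deviation, global or per covariate.
    """
    rng = np.random.default_rng(seed)
    values = items.values.copy()
    meta = list(items.meta)
    for cov, spec in coupling_spec.items():
        unknown = [c for c in spec if c not in values.columns]
        if unknown:
            raise ValueError(f"covariate {cov!r} references unknown item(s): {unknown}")
        sd = noise_sd[cov] if isinstance(noise_sd, dict) else noise_sd
        col = rng.normal(0.0, sd, size=len(values))
        for item, coef in spec.items():
            col = col + coef * values[item].to_numpy(dtype=float)
        values[cov] = col
        meta.append(NodeMeta(name=cov, var_type="continuous",
                             community="environmental"))
    for k in range(1, n_genetic_pcs + 1):
        name = f"PC{k}"
        values[name] = rng.normal(size=len(values))
        meta.append(NodeMeta(name=name, var_type="continuous",
                             community="polygenic"))
    return ItemMatrix(values, meta)


# ---------------------------------------------------------------------------
# the "ukb-like" default cohort
# ---------------------------------------------------------------------------

# Lifetime endorsement rates emulating a large population mental-health
# questionnaire (N ~ 7.8e4): depression items are common, psychosis items
# rare (~96% of participants report none).
UKB_LIKE_MARGINALS = {
    "Sad": 0.406, "Anh": 0.298, "Tir": 0.340, "Wor": 0.213, "Dea": 0.224,
    "Wei": 0.254, "Sle": 0.333, "Cnc": 0.326, "Dei": 0.296,
    "Con": 0.006, "Com": 0.006, "Voi": 0.013, "Vis": 0.027, "Psi": 0.012,
}

_SYMPTOM_COMMUNITY = {
    **{k: "depression" for k in
       ("Sad", "Anh", "Tir", "Wor", "Dea", "Wei", "Sle", "Cnc", "Dei")},
    **{k: "psychosis" for k in ("Con", "Com", "Voi", "Vis", "Psi")},
}

# explicit within-community couplings (hub structure around the core
# depression items; interconnected psychosis cluster)
_SYMPTOM_EDGES = [
    ("Sad", "Anh", 1.0), ("Sad", "Tir", 0.5), ("Sad", "Dea", 0.6),
    ("Sad", "Sle", 0.6), ("Sad", "Cnc", 0.6), ("Sad", "Wei", 0.5),
    ("Sad", "Wor", 0.4), ("Anh", "Tir", 0.6), ("Tir", "Sle", 0.1),
    ("Dea", "Wor", 0.5), ("Wei", "Sle", 0.3), ("Cnc", "Tir", 0.1),
    ("Dei", "Sad", 0.6), ("Dei", "Anh", 0.5), ("Dei", "Wor", 1.0),
    ("Con", "Com", 2.2), ("Voi", "Vis", 1.8), ("Con", "Voi", 2.2),
    ("Com", "Vis", 1.5), ("Psi", "Con", 2.0), ("Psi", "Voi", 0.8),
]

# planted cross-community couplings: worthlessness<->conspiracy beliefs and
# the two impairment nodes.  Bridge couplings are strong by design: the
# rarest symptom endorsement rates are ~0.6%, so weaker cross-community
# couplings would not be detectable under the AND rule at realistic n.
UKB_LIKE_BRIDGE_EDGES = [("Wor", "Con", 3.0), ("Dei", "Psi", 2.2)]

UKB_LIKE_BRIDGES_STEP1 = frozenset({"Wor", "Con", "Dei", "Psi"})
UKB_LIKE_BRIDGES_STEP2 = frozenset({"Wor", "Con", "Dei", "Psi", "Trau"})

# continuous risk factors as linear functions of symptoms / earlier
# covariates (coefficients in noise-sd units); cumulative trauma couples to
# the bridge symptoms and to deprivation, area factors intercorrelate, and
# each polygenic score couples mainly to its own disorder's impairment node.
UKB_LIKE_COVARIATE_SPEC = {
    "IMD": {"Sad": 0.2, "Dea": 0.15},
    "Pol": {"IMD": 0.8},
    "Gre": {"IMD": -0.7, "Pol": -0.3},
    "Trau": {"Wor": 2.2, "Con": 2.4, "Voi": 1.2, "Vis": 1.1, "IMD": 0.2},
    "PRd": {"Dei": 0.25, "Wor": 0.1, "IMD": 0.05, "Trau": 0.05},
    "PRs": {"Psi": 0.25, "PRd": 0.25, "Trau": 0.05},
}

_COVARIATE_COMMUNITY = {
    "Trau": "environmental", "IMD": "environmental", "Pol": "environmental",
    "Gre": "environmental", "PRd": "polygenic", "PRs": "polygenic",
}

UKB_LIKE_SKIP_RULES = [
    SkipRule(gates=("Sad", "Anh"),
             gated=("Tir", "Wor", "Dea", "Wei", "Sle", "Cnc", "Dei")),
    SkipRule(gates=("Con", "Com", "Voi", "Vis"), gated=("Psi",)),
]

PSYCHOSIS_SYMPTOMS = ("Con", "Com", "Voi", "Vis")


@dataclass
class UkbLikeCohort:
    """Bundle returned by :func:`ukb_like_cohort`.

    Attributes
    ----------
    step1_items : ItemMatrix
        14 binary symptom/impairment nodes (skip-logic applied).
    step2_items : ItemMatrix
        The 14 symptom nodes plus 6 risk factors dichotomized at their 75th
        centile (20 binary nodes).
    mgm_items : ItemMatrix
        The 14 symptom nodes plus the 6 risk factors on their continuous
        scale (for the mixed-graphical-model sensitivity analysis).
    full : ItemMatrix
        Everything: symptoms, continuous covariates, dichotomized covariates
        (suffix ``_b`` internally renamed to the plain risk names in
        step2_items) and 5 genetic-PC columns.
    true_graph : IsingGraph
        The 14-node symptom Ising model the binary items were drawn from
        (before skip-logic).
    """

    step1_items: ItemMatrix
    step2_items: ItemMatrix
    mgm_items: ItemMatrix
    full: ItemMatrix
    true_graph: IsingGraph
    bridges_step1: frozenset = UKB_LIKE_BRIDGES_STEP1
    bridges_step2: frozenset = UKB_LIKE_BRIDGES_STEP2


def ukb_like_symptom_graph() -> IsingGraph:
    """The calibrated 14-node symptom Ising model underlying the fixture."""
    names = list(UKB_LIKE_MARGINALS)
    idx = {c: i for i, c in enumerate(names)}
    omega = np.zeros((14, 14))
    for a, b, w in _SYMPTOM_EDGES + UKB_LIKE_BRIDGE_EDGES:
        omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = w
    tau0 = logit(np.array([UKB_LIKE_MARGINALS[c] for c in names]))
    graph = IsingGraph(omega, tau0, names)
    # targets are questionnaire frequencies, i.e. observed after skip logic
    return calibrate_thresholds(
        graph, np.array([UKB_LIKE_MARGINALS[c] for c in names]),
        skip_rules=UKB_LIKE_SKIP_RULES,
    )


def ukb_like_cohort(n: int = 20_000, seed: int = 0,
                    skip_logic: bool = True) -> UkbLikeCohort:
    """Generate the default 20-node synthetic cohort.

    Binary symptoms are exact draws from the calibrated 14-node Ising model;
    skip-logic then zeroes follow-up items for participants endorsing no
    core item.  Continuous risk factors follow
    :data:`UKB_LIKE_COVARIATE_SPEC`; their binary versions are the
    indicator of exceeding the sample 75th centile.
    """
    from .preprocess import dichotomize_q75  # local import avoids a cycle

    graph = ukb_like_symptom_graph()
    items = sample_ising_exact(graph, n, seed=seed)
    # attach community metadata to the symptom nodes
    items = ItemMatrix(
        items.values,
        [NodeMeta(name=c, community=_SYMPTOM_COMMUNITY[c]) for c in graph.node_names],
    )
    if skip_logic:
        items = apply_skip_logic(items, UKB_LIKE_SKIP_RULES)

    full = generate_mixed_covariates(
        items, UKB_LIKE_COVARIATE_SPEC, noise_sd=1.0, seed=seed + 1
    )
    # correct the covariate community labels (generate_mixed_covariates
    # defaults everything to environmental)
    meta = []
    for m in full.meta:
        if m.name in _COVARIATE_COMMUNITY:
            meta.append(NodeMeta(m.name, m.description, "continuous",
                                 _COVARIATE_COMMUNITY[m.name]))
        else:
            meta.append(m)
    full = ItemMatrix(full.values, meta)

    risk = list(UKB_LIKE_COVARIATE_SPEC)
    values = full.values.copy()
    meta = list(full.meta)
    for cov in risk:
        values[cov + "_b"] = dichotomize_q75(values[cov])
        meta.append(NodeMeta(cov + "_b", var_type="binary",
                             community=_COVARIATE_COMMUNITY[cov]))
    full = ItemMatrix(values, meta)

    symptoms = list(UKB_LIKE_MARGINALS)
    step1 = full.subset(symptoms)
    step2 = full.subset(symptoms + [c + "_b" for c in risk])
    step2.values.columns = symptoms + risk
    step2 = ItemMatrix(
        step2.values,
        [m for m in step1.meta]
        + [NodeMeta(c, var_type="binary", community=_COVARIATE_COMMUNITY[c])
           for c in risk],
    )
    mgm = full.subset(symptoms + risk)
    return UkbLikeCohort(step1_items=step1, step2_items=step2,
                         mgm_items=mgm, full=full, true_graph=graph)
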