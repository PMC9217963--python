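"""Synthetic-cohort generator: samplers, calibration, gating, covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from symnet.data import ItemMatrix, NodeMeta
from symnet.simulate import (IsingGraph, SimulationConfig, SkipRule,
                             UKB_LIKE_MARGINALS, apply_skip_logic,
                             calibrate_thresholds, exact_marginals,
                             exact_state_probabilities,
                             generate_mixed_covariates,
                             generate_structured_graph, sample_ising_exact,
                             sample_ising_gibbs, ukb_like_cohort)


def _graph(omega, tau, names=None):
    return IsingGraph(np.asarray(omega, float), np.asarray(tau, float), names)


class TestGenerateStructuredGraph:
    def test_p2_single_edge(self):
        cfg = SimulationConfig(
            p=2, communities={"A": "depression", "B": "psychosis"},
            bridge_edges=[("A", "B", 1.5)], within_density=1.0)
        g = generate_structured_graph(cfg)
        np.testing.assert_array_equal(g.omega, [[0, 1.5], [1.5, 0]])

    def test_cross_community_nonzeros_only_at_bridges(self):
        names = [f"N{i}" for i in range(14)]
        comm = {n: ("depression" if i < 9 else "psychosis")
                for i, n in enumerate(names)}
        cfg = SimulationConfig(p=14, communities=comm, within_density=0.5,
                               bridge_edges=[("N3", "N10", 0.9),
                                             ("N8", "N12", 0.7)], seed=2)
        g = generate_structured_graph(cfg)
        for i in range(14):
            for j in range(i + 1, 14):
                if comm[names[i]] != comm[names[j]]:
                    expected = {("N3", "N10"): 0.9, ("N8", "N12"): 0.7}.get(
                        (names[i], names[j]), 0.0)
                    assert g.omega[i, j] == expected

    def test_deterministic_under_seed(self):
        cfg = dict(p=4, communities={c: "depression" for c in "ABCD"},
                   within_density=0.8, seed=9)
        g1 = generate_structured_graph(SimulationConfig(**cfg))
        g2 = generate_structured_graph(SimulationConfig(**cfg))
        np.testing.assert_array_equal(g1.omega, g2.omega)
        np.testing.assert_array_equal(g1.tau, g2.tau)

    def test_within_community_bridge_pair_rejected(self):
        with pytest.raises(ValueError, match="within community"):
            SimulationConfig(p=2, communities={"A": "depression",
                                               "B": "depression"},
                             bridge_edges=[("A", "B", 1.0)])


class TestExactSampler:
    def test_single_node_zero_threshold(self):
        g = _graph([[0.0]], [0.0])
        items = sample_ising_exact(g, 20_000, seed=1)
        assert abs(items.values.iloc[:, 0].mean() - 0.5) < 0.02

    def test_two_independent_nodes(self):
        g = _graph(np.zeros((2, 2)), [0.0, 0.0])
        items = sample_ising_exact(g, 40_000, seed=2)
        p11 = ((items.values.iloc[:, 0] == 1)
               & (items.values.iloc[:, 1] == 1)).mean()
        assert abs(p11 - 0.25) < 0.01

    def test_p3_state_frequencies_match_enumeration(self):
        rng = np.random.default_rng(4)
        om = np.zeros((3, 3))
        om[0, 1] = om[1, 0] = 0.8
        om[1, 2] = om[2, 1] = -0.5
        g = _graph(om, rng.normal(scale=0.5, size=3))
        probs = exact_state_probabilities(g)
        n = 50_000
        items = sample_ising_exact(g, n, seed=5)
        codes = (items.values.to_numpy()
                 * (2 ** np.arange(3))).sum(axis=1)
        freq = np.bincount(codes, minlength=8) / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) <= 4 * se)

    def test_p_too_large_directs_to_gibbs(self):
        g = _graph(np.zeros((21, 21)), np.zeros(21))
        with pytest.raises(ValueError, match="Gibbs|gibbs"):
            sample_ising_exact(g, 10, seed=0)


class TestGibbsSampler:
    def test_independent_marginals_are_logistic(self):
        tau = np.array([-1.0, 0.0, 0.7])
        g = _graph(np.zeros((3, 3)), tau)
        items = sample_ising_gibbs(g, 20_000, burn_in=30, thin=1, seed=3)
        m = items.values.mean().to_numpy()
        assert np.all(np.abs(m - expit(tau)) < 0.02)

    def test_agrees_with_exact_sampler_p8(self, strong_8node_graph):
        g = strong_8node_graph
        n = 30_000
        exact = sample_ising_exact(g, n, seed=21).values.to_numpy()
        gibbs = sample_ising_gibbs(g, n, burn_in=300, thin=5,
                                   seed=22).values.to_numpy()
        # all pairwise co-endorsement frequencies within 4 two-sample MC SEs
        for i in range(8):
            for j in range(i, 8):
                fe = (exact[:, i] * exact[:, j]).mean()
                fg = (gibbs[:, i] * gibbs[:, j]).mean()
                se = np.sqrt((fe * (1 - fe) + fg * (1 - fg)) / n)
                assert abs(fe - fg) <= 4 * max(se, 1e-4)

    def test_init_zeros_vs_ones_indistinguishable(self):
        om = np.zeros((4, 4))
        om[0, 1] = om[1, 0] = 0.6
        g = _graph(om, np.full(4, -0.5))
        a = sample_ising_gibbs(g, 20_000, burn_in=200, thin=1, seed=7,
                               init="zeros").values.mean()
        b = sample_ising_gibbs(g, 20_000, burn_in=200, thin=1, seed=8,
                               init="ones").values.mean()
        assert np.all(np.abs(a.to_numpy() - b.to_numpy()) < 0.02)

    def test_invalid_burn_in(self, strong_8node_graph):
        with pytest.raises(ValueError):
            sample_ising_gibbs(strong_8node_graph, 10, burn_in=0)


class TestCalibration:
    def test_no_couplings_closed_form(self):
        g = _graph(np.zeros((2, 2)), [2.0, -1.0])
        cal = calibrate_thresholds(g, np.array([0.5, 0.406]))
        assert abs(cal.tau[0]) < 1e-2
        assert abs(cal.tau[1] - logit(0.406)) < 1e-2

    def test_coupled_graph_hits_targets(self):
        rng = np.random.default_rng(10)
        om = np.zeros((6, 6))
        for i in range(5):
            om[i, i + 1] = om[i + 1, i] = rng.uniform(0.3, 1.0)
        targets = rng.uniform(0.15, 0.45, size=6)
        cal = calibrate_thresholds(_graph(om, np.zeros(6)), targets)
        assert np.max(np.abs(exact_marginals(cal) - targets)) < 0.01

    def test_idempotent(self):
        om = np.zeros((4, 4))
        om[0, 1] = om[1, 0] = 0.9
        targets = np.array([0.2, 0.3, 0.4, 0.25])
        cal1 = calibrate_thresholds(_graph(om, np.zeros(4)), targets)
        cal2 = calibrate_thresholds(cal1, targets)
        assert np.max(np.abs(cal2.tau - cal1.tau)) < 0.05

    def test_invalid_targets_rejected(self):
        g = _graph(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            calibrate_thresholds(g, np.array([0.0, 0.5]))


class TestSkipLogic:
    def _items(self, arr, cols):
        return ItemMatrix(pd.DataFrame(arr, columns=cols),
                          [NodeMeta(c) for c in cols])

    def test_gated_forced_zero_when_gates_off(self):
        items = self._items([[0, 0, 1, 1], [1, 0, 1, 0]],
                            ["Sad", "Anh", "Wor", "Dei"])
        out = apply_skip_logic(items, [SkipRule(("Sad", "Anh"),
                                                ("Wor", "Dei"))])
        assert out.values.iloc[0].tolist() == [0, 0, 0, 0]
        assert out.values.iloc[1].tolist() == [1, 0, 1, 0]

    def test_conditional_rate_exactly_zero(self):
        cohort = ukb_like_cohort(n=2000, seed=6)
        v = cohort.step1_items.values
        gate_off = (v["Sad"] == 0) & (v["Anh"] == 0)
        assert gate_off.any()
        assert v.loc[gate_off, "Dei"].sum() == 0

    def test_cyclic_gating_rejected(self):
        items = self._items([[1, 1]], ["A", "B"])
        with pytest.raises(ValueError, match="cyclic"):
            apply_skip_logic(items, [SkipRule(("A",), ("B",)),
                                     SkipRule(("B",), ("A",))])

    def test_unknown_column_rejected(self):
        items = self._items([[1, 1]], ["A", "B"])
        with pytest.raises(ValueError, match="unknown"):
            apply_skip_logic(items, [SkipRule(("A",), ("Z",))])


class TestMixedCovariates:
    def _base(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame({"A": (rng.random(n) < 0.4).astype(int),
                             "B": (rng.random(n) < 0.3).astype(int)})
        return ItemMatrix(vals)

    def test_zero_coupling_independent(self):
        items = self._base()
        out = generate_mixed_covariates(items, {"X": {}}, seed=1)
        r = np.corrcoef(out.values["X"], out.values["A"])[0, 1]
        assert abs(r) < 0.05

    def test_degenerate_noise_reproduces_item(self):
        items = self._base()
        out = generate_mixed_covariates(items, {"X": {"A": 1.0}},
                                        noise_sd=1e-12, seed=1)
        np.testing.assert_allclose(out.values["X"],
                                   out.values["A"].astype(float), atol=1e-9)

    def test_couplings_recovered_by_least_squares(self):
        items = self._base(n=6000, seed=3)
        spec = {"X": {"A": 0.8, "B": -0.5}}
        out = generate_mixed_covariates(items, spec, noise_sd=1.0, seed=4)
        X = np.column_stack([np.ones(out.n), out.values["A"],
                             out.values["B"]])
        y = out.values["X"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (out.n - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert abs(beta[1] - 0.8) < 3 * se[1]
        assert abs(beta[2] + 0.5) < 3 * se[2]

    def test_genetic_pcs_appended(self):
        out = generate_mixed_covariates(self._base(), {}, seed=2)
        assert [f"PC{k}" for k in range(1, 6)] == out.continuous_nodes()

    def test_unknown_item_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_mixed_covariates(self._base(), {"X": {"Zzz": 1.0}})


class TestUkbLikeCohort:
    def test_bit_reproducible(self):
        a = ukb_like_cohort(n=500, seed=42)
        b = ukb_like_cohort(n=500, seed=42)
        pd.testing.assert_frame_equal(a.full.values, b.full.values)

    def test_post_gating_marginals_match_targets(self):
        cohort = ukb_like_cohort(n=50_000, seed=13)
        m = cohort.step1_items.values.mean()
        targets = np.array([UKB_LIKE_MARGINALS[c] for c in m.index])
        # 0.01 generator tolerance plus Monte-Carlo error at n=50k
        assert np.max(np.abs(m.to_numpy() - targets)) < 0.025

    def test_dichotomized_risk_rates_quarterish(self):
        cohort = ukb_like_cohort(n=4000, seed=1)
        rates = cohort.step2_items.values[
            ["Trau", "IMD", "Pol", "Gre", "PRd", "PRs"]].mean()
        assert np.all((rates > 0.2) & (rates <= 0.26))

    def test_node_sets(self):
        cohort = ukb_like_cohort(n=200, seed=0)
        assert cohort.step1_items.p == 14
        assert cohort.step2_items.p == 20
        assert cohort.mgm_items.p == 20
        assert set(cohort.mgm_items.continuous_nodes()) == {
            "Trau", "IMD", "Pol", "Gre", "PRd", "PRs"}
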