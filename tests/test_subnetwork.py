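"""BUM fitting, FDR thresholding, scoring, spanning trees, tree DP, extraction."""
import math

import networkx as nx
import numpy as np
import pytest

from crosstalkkit import (
    BumFit,
    ScoredGraph,
    SimConfig,
    exhaustive_oracle,
    extract_subnetwork,
    fdr_to_tau,
    fit_bum,
    generate_scored_graph,
    max_weight_subtree,
    score_nodes,
    spanning_tree,
)
from conftest import random_connected_graph


def _bum_sample(rng, lam, a, n):
    sig = rng.random(n) > lam
    u = 1.0 - rng.random(n)
    return np.where(sig, u ** (1.0 / a), u)


class TestFitBum:
    def test_parameter_recovery(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fit = fit_bum(_bum_sample(rng, 0.7, 0.3, 10_000))
            errs.append((abs(fit.lambda_mix - 0.7), abs(fit.shape_a - 0.3)))
        med = np.median(errs, axis=0)
        assert med[0] <= 0.1 and med[1] <= 0.1

    def test_uniform_sample_flags_no_signal(self):
        rng = np.random.default_rng(0)
        fit = fit_bum(1.0 - rng.random(5000))
        assert fit.no_signal
        # nodes scoring positive at FDR 0.01 must be rare under the null
        tau = fdr_to_tau(fit, 0.01)
        frac_pos = np.mean(1.0 - rng.random(5000) < tau)
        assert frac_pos <= 0.02

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fit_bum([0.0] + [0.5] * 100)
        with pytest.raises(ValueError):
            fit_bum([0.5] * 10)  # too few points


class TestFdrToTau:
    @pytest.fixture
    def fit(self):
        return BumFit(lambda_mix=0.7, shape_a=0.3, log_likelihood=0.0, n_points=1000)

    def test_fdr_near_one_gives_tau_one(self, fit):
        assert fdr_to_tau(fit, 0.999) == pytest.approx(1.0)

    def test_estimated_fdr_monotone_on_grid(self, fit):
        from crosstalkkit.subnetwork import _estimated_fdr

        xs = np.logspace(-12, 0, 500)
        vals = [_estimated_fdr(fit, x) for x in xs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bisection_matches_closed_form(self, fit):
        # pi0/(lam + (1-lam) x^(a-1)) = fdr  =>  x = (((pi0/fdr)-lam)/(1-lam))^(1/(a-1))
        for fdr in (0.001, 0.01, 0.05, 0.2):
            lam, a = fit.lambda_mix, fit.shape_a
            pi0 = lam + (1 - lam) * a
            closed = (((pi0 / fdr) - lam) / (1 - lam)) ** (1.0 / (a - 1.0))
            assert fdr_to_tau(fit, fdr) == pytest.approx(min(1.0, closed), rel=1e-6)

    def test_pure_signal_closed_form(self):
        # lambda = 0: estFDR(x) = a x^(1-a), so tau = (fdr/a)^(1/(1-a))
        fit = BumFit(lambda_mix=1e-9, shape_a=0.4, log_likelihood=0.0, n_points=100)
        for fdr in (0.01, 0.1):
            expected = (fdr / 0.4) ** (1 / 0.6)
            assert fdr_to_tau(fit, fdr) == pytest.approx(expected, rel=1e-3)

    def test_invalid_fdr(self, fit):
        with pytest.raises(ValueError):
            fdr_to_tau(fit, 0.0)


class TestScoreNodes:
    def _graph(self, pvals):
        g = nx.Graph()
        for i, p in enumerate(pvals):
            g.add_node(f"n{i}", p_value=p)
        for i in range(len(pvals) - 1):
            g.add_edge(f"n{i}", f"n{i+1}")
        return g

    def test_score_arithmetic(self):
        # a=0.5, tau=0.01, p=1e-4 -> s = (-0.5)(ln 1e-4 - ln 1e-2) = 2.3026
        fit = BumFit(0.5, 0.5, 0.0, 100)
        g = self._graph([1e-4, 0.5])
        scored = score_nodes(g, fit, fdr=0.5)
        tau = scored.tau
        s = scored.graph.nodes["n0"]["score"]
        assert s == pytest.approx((0.5 - 1.0) * (math.log(1e-4) - math.log(tau)))
        fixed = (0.5 - 1.0) * (math.log(1e-4) - math.log(1e-2))
        assert fixed == pytest.approx(0.5 * math.log(100)) == pytest.approx(2.302585, abs=1e-6)

    def test_sign_iff_below_tau(self):
        fit = BumFit(0.6, 0.25, 0.0, 100)
        g = self._graph([1e-8, 1e-4, 0.02, 0.4, 1.0])
        scored = score_nodes(g, fit, fdr=0.05)
        for v, d in scored.graph.nodes(data=True):
            assert (d["score"] > 0) == (d["p_value"] < scored.tau)

    def test_edge_distances_nonnegative_and_monotone(self):
        fit = BumFit(0.6, 0.25, 0.0, 100)
        g = self._graph([1e-8, 1e-4, 0.02, 0.4])
        scored = score_nodes(g, fit, fdr=0.05)
        dists = nx.get_edge_attributes(scored.graph, "distance")
        assert all(d >= 0 for d in dists.values())
        # edge between the two best-scoring nodes is the cheapest
        assert dists[("n0", "n1")] == min(dists.values())

    def test_missing_pvalue_named(self):
        g = nx.Graph()
        g.add_node("orphan")
        with pytest.raises(ValueError, match="orphan"):
            score_nodes(g, BumFit(0.5, 0.5, 0.0, 100), 0.01)


class TestSpanningTree:
    def test_triangle_weight(self):
        g = nx.Graph()
        g.add_edge("a", "b", distance=1.0)
        g.add_edge("b", "c", distance=2.0)
        g.add_edge("a", "c", distance=3.0)
        for alg in ("prim", "kruskal"):
            t = spanning_tree(g, alg)
            assert sum(t.edges[e]["distance"] for e in t.edges) == pytest.approx(3.0)

    def test_tree_input_unchanged(self):
        t0 = nx.path_graph(5)
        t0 = nx.relabel_nodes(t0, {i: f"n{i}" for i in t0})
        for u, v in t0.edges:
            t0.edges[u, v]["distance"] = 1.0
        for alg in ("prim", "kruskal"):
            t = spanning_tree(t0, alg)
            assert set(map(frozenset, t.edges)) == set(map(frozenset, t0.edges))

    def test_prim_equals_kruskal_on_random_graphs(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng, int(rng.integers(5, 25)))
            tp = spanning_tree(g, "prim")
            tk = spanning_tree(g, "kruskal")
            wp = sum(g.edges[e]["distance"] for e in tp.edges)
            wk = sum(g.edges[e]["distance"] for e in tk.edges)
            assert wp == pytest.approx(wk, rel=1e-12)
            # distances are continuous draws, hence distinct: identical trees
            assert set(map(frozenset, tp.edges)) == set(map(frozenset, tk.edges))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            spanning_tree(nx.Graph())


class TestMaxWeightSubtree:
    def test_path_bridges_negative_node(self):
        t = nx.path_graph(3)
        scores = {0: 2.0, 1: -1.0, 2: 2.0}
        sub = max_weight_subtree(t, scores)
        assert sub.nodes == frozenset({0, 1, 2}) and sub.total_score == pytest.approx(3.0)

    def test_star_absorbs_positive_leaves(self):
        t = nx.star_graph(3)  # center 0
        scores = {0: -1.0, 1: 1.0, 2: 1.0, 3: 1.0}
        sub = max_weight_subtree(t, scores)
        assert sub.nodes == frozenset({0, 1, 2, 3}) and sub.total_score == pytest.approx(2.0)

    def test_all_negative_returns_best_single_node(self):
        t = nx.path_graph(4)
        scores = {0: -3.0, 1: -0.5, 2: -2.0, 3: -1.0}
        sub = max_weight_subtree(t, scores)
        assert sub.nodes == frozenset({1}) and sub.total_score == pytest.approx(-0.5)

    def test_cycle_rejected(self):
        g = nx.cycle_graph(4)
        with pytest.raises(ValueError):
            max_weight_subtree(g, {v: 1.0 for v in g})

    def test_matches_exhaustive_oracle_on_random_trees(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            t = nx.random_labeled_tree(n, seed=int(rng.integers(1 << 30)))
            t = nx.relabel_nodes(t, {v: f"n{v:02d}" for v in t})
            scores = {v: float(rng.normal(0, 2)) for v in t}
            dp = max_weight_subtree(t, scores)
            orc = exhaustive_oracle(t, scores)
            assert dp.total_score == pytest.approx(orc.total_score, abs=1e-9)


class TestExtractAndOracle:
    def _scored(self, g, scores):
        for v in g:
            g.nodes[v]["score"] = scores[v]
            g.nodes[v]["p_value"] = 0.5
        smax = max(scores.values())
        for u, v in g.edges:
            g.edges[u, v]["distance"] = (smax - scores[u]) + (smax - scores[v])
        return ScoredGraph(g, tau=0.01, fit=BumFit(0.5, 0.5, 0.0, 100))

    def test_single_positive_node(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        sg = self._scored(g, {"n0": -1.0, "n1": 0.5, "n2": -2.0})
        sub = extract_subnetwork(sg)
        assert sub.nodes == frozenset({"n1"})

    def test_all_positive_complete_graph_takes_everything(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        sg = self._scored(g, {v: 1.0 for v in g})
        assert extract_subnetwork(sg).nodes == frozenset(g)
        assert exhaustive_oracle(sg).total_score == pytest.approx(4.0)

    def test_heuristic_never_beats_oracle(self, rng):
        wins = 0
        trials = 40
        for _ in range(trials):
            g = random_connected_graph(rng, int(rng.integers(4, 13)), p=0.35)
            scores = {v: float(rng.normal(-0.5, 1.5)) for v in g}
            sg = self._scored(g, scores)
            heur = extract_subnetwork(sg)
            orc = exhaustive_oracle(sg)
            assert heur.total_score <= orc.total_score + 1e-9
            if abs(heur.total_score - orc.total_score) < 1e-9:
                wins += 1
        assert wins >= 0.9 * trials

    def test_oracle_refuses_large_graphs(self):
        g = nx.path_graph(20)
        with pytest.raises(ValueError):
            exhaustive_oracle(g, {v: 1.0 for v in g})

    def test_planted_module_recovery_strong_signal(self):
        # recoverable regime: Beta(0.05, 1) signal is nearly all below tau
        f1s = []
        for seed in range(8):
            cfg = SimConfig(seed=seed, n_nodes=200, planted_module_size=15, signal_beta_a=0.05)
            g, truth = generate_scored_graph(cfg)
            fit = fit_bum([g.nodes[v]["p_value"] for v in sorted(g.nodes)])
            sub = extract_subnetwork(score_nodes(g, fit, 0.01))
            tp = len(sub.nodes & truth.planted_nodes)
            prec = tp / len(sub.nodes)
            rec = tp / len(truth.planted_nodes)
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert np.median(f1s) >= 0.8
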