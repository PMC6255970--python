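"""Maximal-scoring subnetwork extraction with beta-uniform mixture scoring.

The p-value distribution over network nodes is modelled as a beta-uniform
mixture (BUM)

    f(x) = lambda + (1 - lambda) * a * x**(a - 1),    0 < x <= 1,  a < 1,

a uniform noise component plus a Beta(a, 1) signal component concentrating
near zero.  A target false discovery rate is converted to a p-value
threshold tau, and each node is scored

    s(p) = (a - 1) * (ln p - ln tau),

positive exactly when p < tau.  The maximum-score connected subgraph is
approximated by projecting the graph onto a minimum spanning tree over edge
distances derived from the node scores (independent Prim and Kruskal
implementations cross-check each other), solving the tree exactly by
dynamic programming, and greedily augmenting with positive-scoring
neighbours.  An exhaustive oracle bounds the optimality gap on small
instances.
"""
from __future__ import annotations

import heapq
import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BumFit",
    "ScoredGraph",
    "Subnetwork",
    "fit_bum",
    "fdr_to_tau",
    "score_nodes",
    "spanning_tree",
    "max_weight_subtree",
    "extract_subnetwork",
    "exhaustive_oracle",
]

logger = logging.getLogger(__name__)

#: (lambda, a) optimizer starting points; fixed grid, no randomness.
_BUM_STARTS = ((0.5, 0.5), (0.9, 0.1), (0.1, 0.1), (0.7, 0.3), (0.3, 0.7))
_BOUND_EPS = 1e-9
#: Fits with estimated signal mass (1-lambda)(1-a) below this are flagged
#: "no signal" (the mixture is indistinguishable from Uniform(0,1)).
_NO_SIGNAL_MASS = 1e-3


@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture fit of a p-value sample."""

    lambda_mix: float
    shape_a: float
    log_likelihood: float
    n_points: int
    no_signal: bool = False

    @property
    def pi0_upper(self) -> float:
        """Conservative null-fraction bound: mixture density at p = 1."""
        return self.lambda_mix + (1.0 - self.lambda_mix) * self.shape_a


def _validate_pvalues(p: np.ndarray) -> None:
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")


def fit_bum(p_values: Iterable[float], min_points: int = 50) -> BumFit:
    """Fit the BUM model by bounded maximum likelihood.

    Runs L-BFGS-B from a fixed grid of starting points and returns the best
    optimum.  Requires at least ``min_points`` p-values in (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < min_points:
        raise ValueError(f"need at least {min_points} p-values, got {p.size}")
    _validate_pvalues(p)
    log_p = np.log(p)

    def nll(theta: np.ndarray) -> float:
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * log_p)
        return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

    bounds = [(_BOUND_EPS, 1.0 - _BOUND_EPS)] * 2
    best = None
    for start in _BUM_STARTS:
        res = minimize(nll, np.asarray(start), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam, a = (float(v) for v in best.x)
    signal_mass = (1.0 - lam) * (1.0 - a)
    return BumFit(
        lambda_mix=lam,
        shape_a=a,
        log_likelihood=-float(best.fun),
        n_points=int(p.size),
        no_signal=signal_mass < _NO_SIGNAL_MASS,
    )


def _estimated_fdr(fit: BumFit, x: float) -> float:
    # pi0 * x / F(x) with F the mixture cdf; monotone increasing for a < 1.
    lam, a = fit.lambda_mix, fit.shape_a
    cdf = lam * x + (1.0 - lam) * x**a
    return fit.pi0_upper * x / cdf if cdf > 0 else 1.0


_TAU_FLOOR = 1e-300


def fdr_to_tau(fit: BumFit, fdr: float) -> float:
    """Largest p-value threshold tau with estimated FDR(tau) <= ``fdr``.

    ``estFDR(x) = pi0 * x / F(x)`` is nondecreasing in x for a < 1, so the
    threshold is found by bisection (in log space, to ~1e-12 relative).
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie strictly between 0 and 1")
    if _estimated_fdr(fit, 1.0) <= fdr:
        return 1.0
    if _estimated_fdr(fit, _TAU_FLOOR) > fdr:
        warnings.warn("no threshold satisfies the FDR bound; returning the floor")
        return _TAU_FLOOR
    lo, hi = math.log(_TAU_FLOOR), 0.0  # est <= fdr at lo, > fdr at hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _estimated_fdr(fit, math.exp(mid)) <= fdr:
            lo = mid
        else:
            hi = mid
    return math.exp(lo)


@dataclass
class ScoredGraph:
    """Undirected graph whose nodes carry p-values and BUM scores.

    Node attributes: ``p_value``, ``score``.  Edge attribute: ``distance``
    (nonnegative, small between high-scoring endpoints).
    """

    graph: nx.Graph
    tau: float
    fit: BumFit

    def scores(self) -> dict[str, float]:
        return {v: d["score"] for v, d in self.graph.nodes(data=True)}


def score_nodes(graph: nx.Graph, fit: BumFit, fdr: float = 0.01) -> ScoredGraph:
    """Score every node from its p-value and derive edge distances.

    ``s(p) = (a - 1)(ln p - ln tau)`` is positive iff ``p < tau`` (a < 1).
    The distance of edge (u, v) is the summed score deficit of its
    endpoints from the maximum node score, so minimum spanning trees prefer
    corridors through high-scoring nodes.
    """
    for v, data in graph.nodes(data=True):
        if "p_value" not in data:
            raise ValueError(f"node {v!r} has no p-value")
        if not 0.0 < data["p_value"] <= 1.0:
            raise ValueError(f"node {v!r} has p-value outside (0, 1]")
    tau = fdr_to_tau(fit, fdr)
    g = graph.copy()
    log_tau = math.log(tau)
    for v, data in g.nodes(data=True):
        data["score"] = (fit.shape_a - 1.0) * (math.log(data["p_value"]) - log_tau)
    if g.number_of_nodes():
        s_max = max(d["score"] for _, d in g.nodes(data=True))
        for u, v, data in g.edges(data=True):
            data["distance"] = (s_max - g.nodes[u]["score"]) + (
                s_max - g.nodes[v]["score"]
            )
    return ScoredGraph(graph=g, tau=tau, fit=fit)


# ---------------------------------------------------------------------------
# spanning trees: two independent implementations over the same edge keys
# ---------------------------------------------------------------------------


def _edge_key(g: nx.Graph, u, v) -> tuple:
    a, b = (u, v) if u <= v else (v, u)
    return (g.edges[u, v].get("distance", 1.0), a, b)


def _prim_component(g: nx.Graph, nodes: list) -> list[tuple]:
    root = min(nodes)
    visited = {root}
    heap = [(_edge_key(g, root, nbr), root, nbr) for nbr in g.neighbors(root)]
    heapq.heapify(heap)
    edges = []
    while heap and len(visited) < len(nodes):
        _, u, v = heapq.heappop(heap)
        if v in visited:
            continue
        visited.add(v)
        edges.append((u, v))
        for nbr in g.neighbors(v):
            if nbr not in visited:
                heapq.heappush(heap, (_edge_key(g, v, nbr), v, nbr))
    return edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def spanning_tree(graph: nx.Graph | ScoredGraph, algorithm: str = "kruskal") -> nx.Graph:
    """Minimum spanning tree (forest) over the ``distance`` edge attribute.

    ``algorithm`` selects one of two independent implementations ("prim" or
    "kruskal"); ties are broken by sorted endpoint names in both, so the
    trees agree whenever distances are distinct.
    """
    g = graph.graph if isinstance(graph, ScoredGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot build a spanning tree of an empty graph")
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes(data=True))
    if algorithm == "prim":
        for comp in nx.connected_components(g):
            for u, v in _prim_component(g, sorted(comp)):
                tree.add_edge(u, v, **g.edges[u, v])
    elif algorithm == "kruskal":
        uf = _UnionFind(g.nodes)
        for key in sorted(_edge_key(g, u, v) for u, v in g.edges):
            _, u, v = key
            if uf.union(u, v):
                tree.add_edge(u, v, **g.edges[u, v])
    else:
        raise ValueError("algorithm must be 'prim' or 'kruskal'")
    return tree


@dataclass(frozen=True)
class Subnetwork:
    """A connected node subset with its total score."""

    nodes: frozenset
    total_score: float
    connected: bool = True
    method: str = "tree-dp"

    def __len__(self) -> int:
        return len(self.nodes)


def _better(cand: tuple[float, frozenset], best: tuple[float, frozenset] | None) -> bool:
    # maximize score; tie -> fewer nodes -> lexicographically smallest set
    if best is None:
        return True
    s, nodes = cand
    bs, bnodes = best
    if s != bs:
        return s > bs
    if len(nodes) != len(bnodes):
        return len(nodes) < len(bnodes)
    return sorted(nodes) < sorted(bnodes)


def max_weight_subtree(tree: nx.Graph, scores: Mapping) -> Subnetwork:
    """Exact maximum-score connected subgraph of a tree, by rooted DP.

    ``best(v) = s(v) + sum over children of max(0, best(child))``; the
    answer is the traceback from the best vertex.  The root is the smallest
    node name; ties in the argmax also resolve to the smallest node name.
    """
    n = tree.number_of_nodes()
    if n == 0:
        raise ValueError("empty tree")
    if tree.number_of_edges() != n - 1 or not nx.is_connected(tree):
        raise ValueError("input is not a tree (cycles or disconnected)")
    root = min(tree.nodes)
    parent = {root: None}
    order = [root]
    for u in order:  # BFS; `order` grows while iterating
        for v in tree.neighbors(u):
            if v not in parent:
                parent[v] = u
                order.append(v)
    best: dict = {}
    for v in reversed(order):
        total = float(scores[v])
        for c in tree.neighbors(v):
            if parent.get(c) == v and best[c] > 0.0:
                total += best[c]
        best[v] = total
    top = min((v for v in order), key=lambda v: (-best[v], v))
    members = {top}
    stack = [top]
    while stack:
        v = stack.pop()
        for c in tree.neighbors(v):
            if parent.get(c) == v and c not in members and best[c] > 0.0:
                members.add(c)
                stack.append(c)
    return Subnetwork(frozenset(members), best[top], connected=True, method="tree-dp")


def _augment(g: nx.Graph, scores: Mapping, members: set) -> set:
    # repeatedly absorb positive-scoring neighbours, smallest name first
    members = set(members)
    while True:
        candidates = sorted(
            nbr
            for v in members
            for nbr in g.neighbors(v)
            if nbr not in members and scores[nbr] > 0.0
        )
        if not candidates:
            return members
        members.add(candidates[0])


def extract_subnetwork(
    scored: ScoredGraph, tree_algorithm: str = "kruskal", augment: bool = True
) -> Subnetwork:
    """Heuristic maximum-score connected subgraph of a scored network.

    Per connected component: project onto a minimum spanning tree, solve the
    tree exactly by DP, then greedily add positive-scoring graph neighbours.
    The best-scoring component result wins (ties: fewer nodes, then node
    names).
    """
    g = scored.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot extract a subnetwork from an empty graph")
    scores = scored.scores()
    best: tuple[float, frozenset] | None = None
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        tree = spanning_tree(sub, algorithm=tree_algorithm)
        dp = max_weight_subtree(tree, scores)
        members = set(dp.nodes)
        if augment:
            members = _augment(sub, scores, members)
        total = sum(scores[v] for v in members)
        cand = (total, frozenset(members))
        if _better(cand, best):
            best = cand
    total, members = best
    method = "augmented" if augment else "tree-dp"
    return Subnetwork(members, total, connected=True, method=method)


def exhaustive_oracle(
    graph: nx.Graph | ScoredGraph,
    scores: Mapping | None = None,
    max_nodes: int = 15,
) -> Subnetwork:
    """Provably maximal connected subgraph by exhaustive enumeration.

    Enumerates every nonempty node subset of every connected component and
    keeps the best connected one.  Refuses graphs with more than
    ``max_nodes`` nodes.  Ties break toward fewer nodes, then the
    lexicographically smallest node set.
    """
    if isinstance(graph, ScoredGraph):
        scores = graph.scores()
        graph = graph.graph
    if scores is None:
        raise ValueError("scores are required when passing a bare graph")
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n > max_nodes:
        raise ValueError(f"refusing exhaustive enumeration of {n} > {max_nodes} nodes")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    best: tuple[float, frozenset] | None = None
    for mask in range(1, 1 << n):
        # connectivity check: BFS over the masked adjacency
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            f = frontier
            while f:
                bit = f & -f
                nxt |= adj[bit.bit_length() - 1]
                f ^= bit
            frontier = nxt & mask & ~seen
            seen |= frontier
        if seen != mask:
            continue
        members = frozenset(nodes[i] for i in range(n) if mask >> i & 1)
        total = sum(scores[v] for v in members)
        if _better((total, members), best):
            best = (total, members)
    total, members = best
    return Subnetwork(members, total, connected=True, method="exhaustive")
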