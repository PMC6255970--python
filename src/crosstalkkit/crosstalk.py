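"""Pathway cross-talk network construction.

Two pathways "cross-talk" when their member-gene sets overlap more than
chance within the candidate-gene universe.  The stage mirrors the standard
screen: drop pathways with fewer than 3 candidate genes, keep pathway pairs
sharing at least 3 genes, test each pair's overlap with the one-sided Fisher
exact test, correct with BH, rank by the Jaccard (JC) and overlap (OC)
coefficients

    JC = |A n B| / |A u B|        OC = |A n B| / min(|A|, |B|)

and keep the significant, high-ranking pairs as network edges.  Nodes of one
functional class form a "major module" when enough of them survive into the
network.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import bh_adjust, hypergeom_upper_tail
from .pathways import PathwayDB

__all__ = [
    "PathwayPairRecord",
    "CrosstalkNetwork",
    "jaccard",
    "overlap_coefficient",
    "filter_min_genes",
    "build_pairs",
    "pair_fisher",
    "score_pairs",
    "rank_and_select",
    "build_network",
]

#: Smallest number of same-class network nodes that counts as a major module.
MAJOR_MODULE_MIN_NODES = 4


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """``|a n b| / |a u b|``; both sets must be nonempty."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValueError("jaccard requires nonempty sets")
    return len(sa & sb) / len(sa | sb)


def overlap_coefficient(a: Iterable[str], b: Iterable[str]) -> float:
    """``|a n b| / min(|a|, |b|)``; both sets must be nonempty."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient requires nonempty sets")
    return len(sa & sb) / min(len(sa), len(sb))


def filter_min_genes(db: PathwayDB, min_genes: int = 3) -> PathwayDB:
    """Drop pathways with fewer than ``min_genes`` interacting genes."""
    return db.filter_min_genes(min_genes)


@dataclass(frozen=True)
class PathwayPairRecord:
    """One candidate cross-talk edge between two pathways."""

    pair: tuple[str, str]
    shared: int
    jc: float
    oc: float
    p_raw: float | None = None
    p_adj: float | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if self.shared < 1:
            raise ValueError("pair records require at least one shared gene")


def build_pairs(
    db: PathwayDB, min_shared: int = 3
) -> tuple[PathwayDB, list[PathwayPairRecord]]:
    """All unordered pathway pairs sharing at least ``min_shared`` genes.

    Returns the "valid" DB (pathways participating in at least one surviving
    pair) and the deduplicated pair list with JC/OC filled in.  Expects a DB
    already filtered on per-pathway gene counts.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    names = sorted(db.names)
    pairs: list[PathwayPairRecord] = []
    in_pair: set[str] = set()
    for i, a in enumerate(names):
        ga = db.genes(a)
        for b in names[i + 1 :]:
            gb = db.genes(b)
            shared = len(ga & gb)
            if shared >= min_shared:
                pairs.append(
                    PathwayPairRecord(
                        (a, b), shared, jaccard(ga, gb), overlap_coefficient(ga, gb)
                    )
                )
                in_pair.update((a, b))
    valid = db.subset([n for n in db.names if n in in_pair])
    return valid, pairs


def pair_fisher(
    a: Iterable[str], b: Iterable[str], background_size: int
) -> float:
    """One-sided Fisher p for the overlap of two gene sets.

    The 2x2 table margins are ``(|A|, |B|)`` out of ``background_size``
    genes; the p-value is the hypergeometric upper tail at ``|A n B|``.
    """
    sa, sb = frozenset(a), frozenset(b)
    if len(sa | sb) > background_size:
        raise ValueError("background smaller than |A u B|")
    return hypergeom_upper_tail(len(sa & sb), len(sa), len(sb), background_size)


def score_pairs(
    pairs: Sequence[PathwayPairRecord],
    db: PathwayDB,
    background_size: int | None = None,
) -> list[PathwayPairRecord]:
    """Attach Fisher p-values and BH-adjusted values to pair records.

    The default test universe is the union of genes covered by the valid
    pathways (the candidate genes the cross-talk analysis operates on); BH
    runs over all tested pairs.
    """
    if not pairs:
        return []
    N = len(db.universe) if background_size is None else int(background_size)
    raw = [
        pair_fisher(db.genes(p.pair[0]), db.genes(p.pair[1]), N) for p in pairs
    ]
    adj = bh_adjust(raw)
    return [
        replace(p, p_raw=float(pr), p_adj=float(pa))
        for p, pr, pa in zip(pairs, raw, adj)
    ]


_RANK_METHODS = ("mean", "jc", "oc")


def rank_and_select(
    pairs: Sequence[PathwayPairRecord],
    fdr_max: float = 0.01,
    min_shared: int = 3,
    top_fraction: float | None = None,
    rank_method: str = "mean",
) -> list[PathwayPairRecord]:
    """Rank pairs and keep the significant, high-scoring ones as edges.

    Pairs must carry ``p_adj`` (see :func:`score_pairs`).  Selection keeps
    pairs with ``p_adj < fdr_max`` and ``shared >= min_shared``, sorts them
    by descending rank score (mean of JC and OC by default; ties broken by
    ascending ``p_adj``, then pair name), and, if ``top_fraction`` is given,
    truncates to ``ceil(top_fraction * n_selected)`` edges.
    """
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must lie in (0, 1]")
    if top_fraction is not None and not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if rank_method not in _RANK_METHODS:
        raise ValueError(f"rank_method must be one of {_RANK_METHODS}")

    def score(p: PathwayPairRecord) -> float:
        if rank_method == "jc":
            return p.jc
        if rank_method == "oc":
            return p.oc
        return 0.5 * (p.jc + p.oc)

    scored = []
    for p in pairs:
        if p.p_adj is None:
            raise ValueError(f"pair {p.pair} has no adjusted p-value")
        scored.append(replace(p, rank_score=score(p)))
    selected = [p for p in scored if p.p_adj < fdr_max and p.shared >= min_shared]
    selected.sort(key=lambda p: (-p.rank_score, p.p_adj, p.pair))
    if not selected:
        warnings.warn("no pathway pair passed the selection thresholds")
        return []
    if top_fraction is not None:
        selected = selected[: math.ceil(top_fraction * len(selected))]
    return selected


@dataclass
class CrosstalkNetwork:
    """Selected cross-talk edges as an attributed undirected graph."""

    graph: nx.Graph
    edges: list[PathwayPairRecord]
    modules: dict[str, frozenset[str]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def build_network(
    edges: Sequence[PathwayPairRecord],
    db: PathwayDB,
    module_min_nodes: int = MAJOR_MODULE_MIN_NODES,
) -> CrosstalkNetwork:
    """Assemble the cross-talk network from selected pair records.

    Nodes carry functional class and gene count; major modules are the
    functional classes represented by at least ``module_min_nodes`` network
    nodes.  The summary reports node/edge counts, average degree (2E/V) and
    the average local clustering coefficient (nodes of degree < 2
    contribute 0).
    """
    if not edges:
        warnings.warn("building a network from an empty edge list")
    g = nx.Graph()
    for rec in edges:
        a, b = rec.pair
        for name in (a, b):
            if name not in g:
                g.add_node(
                    name,
                    functional_class=db.functional_class(name),
                    n_genes=len(db.genes(name)),
                    ko=db.ko(name) or "",
                )
        g.add_edge(
            a,
            b,
            shared=rec.shared,
            jc=rec.jc,
            oc=rec.oc,
            p_raw=rec.p_raw if rec.p_raw is not None else float("nan"),
            p_adj=rec.p_adj if rec.p_adj is not None else float("nan"),
            rank_score=rec.rank_score if rec.rank_score is not None else float("nan"),
        )

    by_class: dict[str, set[str]] = {}
    for node, data in g.nodes(data=True):
        by_class.setdefault(data["functional_class"], set()).add(node)
    modules = {
        cls: frozenset(nodes)
        for cls, nodes in sorted(by_class.items())
        if len(nodes) >= module_min_nodes
    }

    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    summary = {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "average_degree": (2.0 * n_edges / n_nodes) if n_nodes else 0.0,
        "average_clustering": nx.average_clustering(g) if n_nodes else 0.0,
        "n_major_modules": len(modules),
    }
    return CrosstalkNetwork(graph=g, edges=list(edges), modules=modules, summary=summary)


def edge_table(edges: Sequence[PathwayPairRecord]) -> pd.DataFrame:
    """Edge records as a DataFrame (one row per selected pair)."""
    return pd.DataFrame(
        [
            {
                "pathway_a": p.pair[0],
                "pathway_b": p.pair[1],
                "shared": p.shared,
                "jc": p.jc,
                "oc": p.oc,
                "p_raw": p.p_raw,
                "p_adj": p.p_adj,
                "rank_score": p.rank_score,
            }
            for p in edges
        ],
        columns=[
            "pathway_a",
            "pathway_b",
            "shared",
            "jc",
            "oc",
            "p_raw",
            "p_adj",
            "rank_score",
        ],
    )
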