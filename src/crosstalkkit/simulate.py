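"""Synthetic gene universes, pathway collections, candidate sets and PPI graphs.

The generator emulates the statistical structure the downstream stages
assume for a sorghum-style drought candidate-gene study: a genome-scale
gene universe with locus IDs of the form ``Sb{chrom}g{6 digits}``, a
pathway collection whose members concentrate in a drought-associated gene
subpool (so pathway pairs can share candidate genes), a prioritized
candidate set over-represented in designated pathways at a controlled odds
ratio, and an undirected PPI graph with a planted connected module whose
p-values follow a Beta(a, 1) signal component against a Uniform(0, 1)
background.

All randomness flows from the single integer ``SimConfig.seed`` through
spawned :class:`numpy.random.SeedSequence` children (one per generated
artifact), so each artifact is reproducible independently of the others.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .pathways import PathwayDB, PathwayEntry

__all__ = [
    "SimConfig",
    "TruthLabels",
    "FUNCTIONAL_CLASSES",
    "generate_universe",
    "generate_pathway_db",
    "generate_candidate_set",
    "generate_scored_graph",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a SimConfig cannot produce the requested artifact."""


#: Functional-class vocabulary with sampling weights proportional to how
#: often each class occurs among the cross-talk pathways of a sorghum
#: drought study (amino-acid and carbohydrate metabolism dominate).
FUNCTIONAL_CLASSES: tuple[tuple[str, int], ...] = (
    ("Amino acid metabolism", 10),
    ("Carbohydrate metabolism", 8),
    ("Xenobiotics biodegradation and metabolism", 5),
    ("Metabolism of other amino acids", 3),
    ("Metabolism of terpenoids and polyketides", 3),
    ("Lipid metabolism", 2),
    ("Energy metabolism", 2),
    ("Nucleotide metabolism", 2),
    ("Metabolism of cofactors and vitamins", 2),
    ("Biosynthesis of other secondary metabolites", 2),
    ("Carbon metabolism", 1),
    ("Environmental Information Processing; Signal transduction", 1),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the scale of the drought candidate-gene inputs: a
    ~10^4-gene universe, 69 pathways of 3-28 genes drawn from a 250-gene
    drought-associated subpool, a 133-gene prioritized candidate set
    strongly over-represented in the designated (default: all) pathways,
    and a 266-node PPI graph with a 15-node planted module.
    """

    seed: int = 0
    # universe / pathways
    n_genes: int = 10_000
    n_pathways: int = 69
    pathway_size_range: tuple[int, int] = (3, 28)
    overlap_rate: float = 0.5
    pathway_pool_size: int | None = 250
    # candidate set
    n_candidates: int = 133
    enriched_pathway_ids: tuple[str, ...] | None = None  # None -> all pathways
    enrichment_odds: float = 100.0
    # PPI graph
    n_nodes: int = 266
    edge_model: str = "random-uniform"
    mean_degree: float = 4.0
    planted_module_size: int = 15
    signal_beta_a: float = 0.2

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if lo < 3:
            raise ConfigError("pathway_size_range minimum must be >= 3")
        if hi < lo:
            raise ConfigError("pathway_size_range must be (min, max) with min <= max")
        pool = self.pathway_pool_size
        if pool is not None and not 0 < pool <= self.n_genes:
            raise ConfigError("pathway_pool_size must lie in (0, n_genes]")
        if hi > (pool if pool is not None else self.n_genes):
            raise ConfigError("pathway sizes exceed the available gene pool")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ConfigError("overlap_rate must lie in [0, 1]")
        if self.n_candidates > self.n_genes:
            raise ConfigError("n_candidates exceeds the gene universe")
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds must be positive")
        if self.edge_model not in ("random-uniform", "preferential-attachment"):
            raise ConfigError(f"unknown edge model: {self.edge_model!r}")
        if self.planted_module_size > self.n_nodes:
            raise ConfigError("planted_module_size exceeds n_nodes")
        if not 0.0 < self.signal_beta_a < 1.0:
            raise ConfigError("signal_beta_a must lie in (0, 1)")
        if self.n_nodes > self.n_genes:
            raise ConfigError("n_nodes exceeds the gene universe")


@dataclass
class TruthLabels:
    """Ground truth serialized alongside simulated data."""

    enriched_pathways: frozenset[str] = frozenset()
    planted_nodes: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "enriched_pathways": sorted(self.enriched_pathways),
            "planted_nodes": sorted(self.planted_nodes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthLabels":
        return cls(
            frozenset(d.get("enriched_pathways", ())),
            frozenset(d.get("planted_nodes", ())),
        )


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_universe(cfg: SimConfig) -> list[str]:
    """Deterministic sorghum-style locus IDs, ``Sb{chrom:02d}g{6 digits}``.

    IDs depend only on ``n_genes`` (gene identity is an arbitrary label);
    the randomness budget is spent on memberships, not on names.
    """
    return [f"Sb{(i % 10) + 1:02d}g{100_000 + i // 10:06d}" for i in range(cfg.n_genes)]


def _pathway_names(cfg: SimConfig) -> list[str]:
    return [f"pathway{i + 1:03d}" for i in range(cfg.n_pathways)]


def generate_pathway_db(cfg: SimConfig) -> PathwayDB:
    """Draw ``n_pathways`` gene sets from the universe (or its subpool).

    Consecutive pathways (1,2), (3,4), ... are "designated pairs": each
    pair shares a core of ``round(overlap_rate * min(size_i, size_j))``
    genes, giving direct control of the expected overlap.  With
    ``overlap_rate = 0`` memberships are independent draws, so pairwise
    overlap sits at the hypergeometric chance level.
    """
    cfg.validate()
    rng, _, _ = _rngs(cfg)
    universe = generate_universe(cfg)
    pool = universe if cfg.pathway_pool_size is None else universe[: cfg.pathway_pool_size]
    pool_arr = np.asarray(pool)
    names = _pathway_names(cfg)
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)

    class_names = [c for c, _ in FUNCTIONAL_CLASSES]
    class_w = np.asarray([w for _, w in FUNCTIONAL_CLASSES], dtype=float)
    classes = rng.choice(class_names, size=cfg.n_pathways, p=class_w / class_w.sum())

    members: list[np.ndarray] = [None] * cfg.n_pathways
    i = 0
    while i < cfg.n_pathways:
        if i + 1 < cfg.n_pathways:
            si, sj = int(sizes[i]), int(sizes[i + 1])
            core_size = int(round(cfg.overlap_rate * min(si, sj)))
            core = rng.choice(pool_arr, size=core_size, replace=False)
            rest_pool = np.setdiff1d(pool_arr, core)
            # remainders drawn independently, so overlap beyond the shared
            # core stays at the hypergeometric chance level
            members[i] = np.concatenate(
                [core, rng.choice(rest_pool, size=si - core_size, replace=False)]
            )
            members[i + 1] = np.concatenate(
                [core, rng.choice(rest_pool, size=sj - core_size, replace=False)]
            )
            i += 2
        else:
            members[i] = rng.choice(pool_arr, size=int(sizes[i]), replace=False)
            i += 1

    entries = {
        name: PathwayEntry(
            frozenset(str(g) for g in genes),
            functional_class=str(cls),
            ko=f"ko{idx + 1:05d}",
        )
        for idx, (name, genes, cls) in enumerate(zip(names, members, classes))
    }
    return PathwayDB(entries)


def generate_candidate_set(
    db: PathwayDB, cfg: SimConfig
) -> tuple[frozenset[str], TruthLabels]:
    """Sample the prioritized candidate set from the universe.

    Sampling is without replacement with per-gene weights: genes belonging
    to any designated "enriched" pathway carry weight ``enrichment_odds``,
    all others weight 1 (weighted reservoir via Gumbel keys, which matches
    sequential weighted draws).  ``enrichment_odds = 1`` reduces to a
    uniform draw, the null used for calibration.
    """
    cfg.validate()
    enriched = (
        tuple(db.names) if cfg.enriched_pathway_ids is None else tuple(cfg.enriched_pathway_ids)
    )
    unknown = set(enriched) - set(db.names)
    if unknown:
        raise ConfigError(f"enriched_pathway_ids not in the collection: {sorted(unknown)}")
    _, rng, _ = _rngs(cfg)
    universe = generate_universe(cfg)
    if cfg.n_candidates == 0:
        return frozenset(), TruthLabels(enriched_pathways=frozenset(enriched))
    enriched_genes: set[str] = set()
    for name in enriched:
        enriched_genes |= db.genes(name)
    weights = np.where(np.isin(universe, sorted(enriched_genes)), cfg.enrichment_odds, 1.0)
    keys = np.log(weights) + rng.gumbel(size=len(universe))
    top = np.argsort(keys, kind="stable")[-cfg.n_candidates :]
    candidates = frozenset(universe[i] for i in top)
    return candidates, TruthLabels(enriched_pathways=frozenset(enriched))


def _random_uniform_edges(
    rng: np.random.Generator, nodes: Sequence[str], n_edges: int
) -> set[tuple[str, str]]:
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    n_edges = min(n_edges, max_edges)
    edges: set[tuple[str, str]] = set()
    while len(edges) < n_edges:
        u, v = rng.integers(0, n, size=2)
        if u == v:
            continue
        a, b = (nodes[u], nodes[v]) if nodes[u] < nodes[v] else (nodes[v], nodes[u])
        edges.add((a, b))
    return edges


def generate_scored_graph(cfg: SimConfig) -> tuple[nx.Graph, TruthLabels]:
    """Generate the PPI graph with a planted, connected signal module.

    Returns an undirected :class:`networkx.Graph` whose nodes carry a
    ``p_value`` attribute: planted nodes draw ``p ~ Beta(a, 1)`` (signal
    near zero for a < 1), the rest ``p ~ Uniform(0, 1]``.  The planted
    module is made connected by adding a random tree over its members;
    disconnected graph components are bridged deterministically through
    their smallest node IDs (extra edges are logged).
    """
    cfg.validate()
    _, _, rng = _rngs(cfg)
    universe = generate_universe(cfg)
    nodes = sorted(str(g) for g in rng.choice(np.asarray(universe), size=cfg.n_nodes, replace=False))

    g = nx.Graph()
    g.add_nodes_from(nodes)
    if cfg.n_nodes > 1:
        if cfg.edge_model == "random-uniform":
            g.add_edges_from(
                _random_uniform_edges(rng, nodes, int(round(cfg.mean_degree * cfg.n_nodes / 2)))
            )
        else:  # preferential-attachment
            m = max(1, int(round(cfg.mean_degree / 2)))
            ba = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=rng)
            g.add_edges_from((nodes[u], nodes[v]) for u, v in ba.edges)

    planted = sorted(
        str(v) for v in rng.choice(np.asarray(nodes), size=cfg.planted_module_size, replace=False)
    )
    if len(planted) > 1:  # random tree over the module guarantees connectivity
        order = list(rng.permutation(planted))
        for i, v in enumerate(order[1:], start=1):
            u = order[int(rng.integers(0, i))]
            g.add_edge(u, v)

    components = sorted(nx.connected_components(g), key=min)
    if len(components) > 1:
        anchor = min(components[0])
        for comp in components[1:]:
            g.add_edge(anchor, min(comp))
        logger.info("bridged %d disconnected components", len(components) - 1)

    planted_set = set(planted)
    for v in nodes:
        u = 1.0 - rng.random()  # in (0, 1]
        if v in planted_set:
            g.nodes[v]["p_value"] = float(u ** (1.0 / cfg.signal_beta_a))
        else:
            g.nodes[v]["p_value"] = float(u)
    return g, TruthLabels(planted_nodes=frozenset(planted))
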