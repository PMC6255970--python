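"""Readers and writers for the formats the pipeline touches.

Pathway collections travel as GMT (name, description, members...; the
functional class rides in the description field as ``class=<label>`` so the
files stay valid for other GMT consumers), candidate lists as one-column
TSV with a header, PPI networks as an edge-list TSV plus a node/p-value
TSV, and networks are exported as SIF and GraphML for Cytoscape import.
All writers emit deterministic (sorted) line order; all readers reject
malformed input with informative errors rather than coercing silently.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .crosstalk import CrosstalkNetwork, PathwayPairRecord, edge_table
from .pathways import PathwayDB, PathwayEntry
from .simulate import TruthLabels

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_candidates",
    "write_candidates",
    "read_scored_network",
    "write_network_tsv",
    "write_sif",
    "write_graphml",
    "write_truth",
    "read_truth",
    "read_config",
    "write_config",
]

logger = logging.getLogger(__name__)


def _describe(entry: PathwayEntry) -> str:
    desc = f"class={entry.functional_class}"
    if entry.ko:
        desc += f";ko={entry.ko}"
    return desc


def _parse_description(desc: str) -> tuple[str, str | None]:
    if "=" not in desc:
        return desc, None
    cls, ko = "", None
    for part in desc.split(";"):
        key, _, value = part.partition("=")
        if key == "class":
            cls = value
        elif key == "ko" and value:
            ko = value
    return cls, ko


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    """One pathway per line: name, description, tab-separated sorted members."""
    with open(path, "w") as fh:
        for name in db.names:
            entry = db[name]
            fields = [name, _describe(entry), *sorted(entry.genes)]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str | Path) -> PathwayDB:
    """Parse a GMT file; duplicate members are deduplicated with a warning,
    duplicate pathway names are an error."""
    entries: dict[str, PathwayEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in entries:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            if len(set(members)) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} deduplicated")
            cls, ko = _parse_description(desc)
            entries[name] = PathwayEntry(frozenset(members), cls, ko)
    if not entries:
        warnings.warn(f"{path}: empty GMT file")
    return PathwayDB(entries)


def write_candidates(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\n")
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_candidates(path: str | Path) -> frozenset[str]:
    """Read a one-column (header + gene IDs) candidate list, deduplicated."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: missing header line")
    rows = [ln.split("\t")[0] for ln in lines[1:]]
    genes = frozenset(rows)
    if len(genes) < len(rows):
        logger.info("%s: %d duplicate gene IDs removed", path, len(rows) - len(genes))
    if not genes:
        warnings.warn(f"{path}: no genes after the header")
    logger.info("%s: read %d candidate genes", path, len(genes))
    return genes


def write_scored_network(graph: nx.Graph, edges_path: str | Path, pvalues_path: str | Path) -> None:
    """Write the edge list (node_a, node_b, weight) and node p-value table."""
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\t1\n")
    with open(pvalues_path, "w") as fh:
        fh.write("node\tp_value\n")
        for v in sorted(graph.nodes):
            fh.write(f"{v}\t{graph.nodes[v]['p_value']:.17g}\n")


def read_scored_network(edges_path: str | Path, pvalues_path: str | Path) -> nx.Graph:
    """Assemble a simple undirected graph with per-node p-values.

    Self-loops are dropped with a warning; edges listed in both directions
    collapse to one; a node appearing in the edge list without a p-value is
    an error naming the node, as is a p-value outside (0, 1].
    """
    pvals: dict[str, float] = {}
    with open(pvalues_path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{pvalues_path}: missing header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{pvalues_path}:{lineno}: expected node<TAB>p_value")
            node, raw = fields[0], fields[1]
            p = float(raw)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{pvalues_path}:{lineno}: node {node!r} has p={p} outside (0, 1]")
            pvals[node] = p
    g = nx.Graph()
    g.add_nodes_from((v, {"p_value": p}) for v, p in pvals.items())
    with open(edges_path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{edges_path}:{lineno}: expected node_a<TAB>node_b")
            u, v = fields[0], fields[1]
            if u == v:
                warnings.warn(f"{edges_path}:{lineno}: self-loop on {u!r} dropped")
                continue
            for node in (u, v):
                if node not in pvals:
                    raise ValueError(f"{edges_path}:{lineno}: node {node!r} has no p-value")
            g.add_edge(u, v)
    return g


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.3e}" if (x != 0 and abs(x) < 1e-3) else f"{x:.4g}"
    return str(x)


def write_network_tsv(net: CrosstalkNetwork, path: str | Path) -> None:
    """Edge table TSV with p-values in 3-significant-digit scientific form."""
    df = edge_table(net.edges)
    for col in ("p_raw", "p_adj"):
        df[col] = df[col].map(lambda v: f"{v:.3e}" if pd.notna(v) else "")
    for col in ("jc", "oc", "rank_score"):
        df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    df.to_csv(path, sep="\t", index=False)


def write_sif(graph: nx.Graph, path: str | Path, interaction: str = "crosstalk") -> None:
    """``nodeA<TAB>interaction<TAB>nodeB``, sorted; isolated nodes on their own line."""
    lines = [f"{u}\t{interaction}\t{v}" for u, v in (tuple(sorted(e)) for e in graph.edges)]
    lines += [str(v) for v in graph.nodes if graph.degree[v] == 0]
    with open(path, "w") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_truth(truth: TruthLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> TruthLabels:
    with open(path) as fh:
        return TruthLabels.from_dict(json.load(fh))


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
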