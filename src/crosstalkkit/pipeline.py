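"""End-to-end driver: simulate -> enrich -> cross-talk -> subnetwork.

Every run serializes its configuration and seed next to its outputs, so a
result directory can be regenerated byte-identically.  The summary JSON
reports the filter cascade in pipeline order: pathways in, >=3-gene
survivors, valid pathways, pairs, selected edges, subnetwork size.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as ckio
from .crosstalk import (
    build_network,
    build_pairs,
    filter_min_genes,
    rank_and_select,
    score_pairs,
)
from .enrichment import enrich, enrichment_table
from .pathways import PathwayDB
from .simulate import (
    SimConfig,
    generate_candidate_set,
    generate_pathway_db,
    generate_scored_graph,
)
from .subnetwork import extract_subnetwork, fit_bum, score_nodes

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage toggles, input paths and thresholds for one pipeline run.

    With no input paths set, inputs are simulated from ``sim`` (which
    defaults to the study-shaped :class:`SimConfig` reseeded with ``seed``).
    """

    outdir: str = "crosstalkkit-run"
    seed: int = 0
    # inputs (None -> simulate)
    gmt_path: str | None = None
    candidates_path: str | None = None
    edges_path: str | None = None
    pvalues_path: str | None = None
    # stage toggles
    run_enrich: bool = True
    run_crosstalk: bool = True
    run_subnet: bool = True
    # thresholds
    min_genes: int = 3
    min_shared: int = 3
    enrich_alpha: float = 0.05
    pair_fdr: float = 0.01
    subnet_fdr: float = 0.01
    top_fraction: float | None = None
    background_size: int | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["pathway_size_range"] = list(d["sim"]["pathway_size_range"])
        if d["sim"]["enriched_pathway_ids"] is not None:
            d["sim"]["enriched_pathway_ids"] = list(d["sim"]["enriched_pathway_ids"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if "pathway_size_range" in sim:
            sim["pathway_size_range"] = tuple(sim["pathway_size_range"])
        if sim.get("enriched_pathway_ids") is not None:
            sim["enriched_pathway_ids"] = tuple(sim["enriched_pathway_ids"])
        return cls(sim=SimConfig(**sim), **d)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages, write all outputs, return the summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ckio.write_config(cfg.to_dict(), out / "config.yaml")
    summary: dict = {"seed": cfg.seed, "stages": []}

    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)

    # ---- inputs -------------------------------------------------------
    if cfg.gmt_path:
        db = ckio.read_gmt(cfg.gmt_path)
    else:
        db = _stage("simulate")(generate_pathway_db)(sim)
        ckio.write_gmt(db, out / "pathways.gmt")
    if cfg.candidates_path:
        candidates = ckio.read_candidates(cfg.candidates_path)
        truth = None
    else:
        candidates, truth = _stage("simulate")(generate_candidate_set)(db, sim)
        ckio.write_candidates(candidates, out / "candidates.tsv")
    if truth is not None:
        ckio.write_truth(truth, out / "truth_candidates.json")
    summary["n_pathways_in"] = len(db)
    summary["n_candidates"] = len(candidates)
    background = cfg.background_size or (
        sim.n_genes if not cfg.gmt_path else len(db.universe | candidates)
    )

    # ---- enrichment ---------------------------------------------------
    enriched_names = list(db.names)
    if cfg.run_enrich:
        records = _stage("enrich")(enrich)(candidates, db, background, cfg.enrich_alpha)
        enrichment_table(records).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        enriched_names = [r.term_id for r in records if r.p_adj < cfg.enrich_alpha]
        summary["stages"].append("enrich")
        summary["n_terms_tested"] = len(records)
        summary["n_terms_enriched"] = len(enriched_names)
    else:
        summary["stages"].append("enrich:skipped")

    # ---- cross-talk ---------------------------------------------------
    if cfg.run_crosstalk:
        pool = db.subset(enriched_names) if cfg.run_enrich else db
        restricted = pool.restrict_to(candidates)
        sized = filter_min_genes(restricted, cfg.min_genes)
        valid, pairs = build_pairs(sized, cfg.min_shared)
        pairs = score_pairs(pairs, valid)
        edges = rank_and_select(
            pairs, cfg.pair_fdr, cfg.min_shared, cfg.top_fraction
        ) if pairs else []
        net = build_network(edges, valid) if edges else None
        summary["stages"].append("crosstalk")
        summary["n_pathways_enriched_in_candidates"] = len(restricted)
        summary["n_pathways_min_genes"] = len(sized)
        summary["n_pathways_valid"] = len(valid)
        summary["n_pairs"] = len(pairs)
        summary["n_edges_selected"] = len(edges)
        if net is not None:
            ckio.write_network_tsv(net, out / "crosstalk_edges.tsv")
            ckio.write_sif(net.graph, out / "crosstalk.sif")
            ckio.write_graphml(net.graph, out / "crosstalk.graphml")
            with open(out / "crosstalk_modules.tsv", "w") as fh:
                fh.write("functional_class\tn_nodes\tpathways\n")
                for cls, nodes in net.modules.items():
                    fh.write(f"{cls}\t{len(nodes)}\t{','.join(sorted(nodes))}\n")
            summary["network"] = net.summary
    else:
        summary["stages"].append("crosstalk:skipped")

    # ---- subnetwork ---------------------------------------------------
    if cfg.run_subnet:
        if cfg.edges_path and cfg.pvalues_path:
            graph = ckio.read_scored_network(cfg.edges_path, cfg.pvalues_path)
            gtruth = None
        else:
            graph, gtruth = _stage("simulate")(generate_scored_graph)(sim)
            ckio.write_scored_network(graph, out / "ppi_edges.tsv", out / "ppi_pvalues.tsv")
        if gtruth is not None:
            ckio.write_truth(gtruth, out / "truth_planted.json")
        pvals = [graph.nodes[v]["p_value"] for v in sorted(graph.nodes)]
        fit = _stage("subnet")(fit_bum)(pvals)
        scored = score_nodes(graph, fit, cfg.subnet_fdr)
        subnet = extract_subnetwork(scored)
        with open(out / "subnetwork_nodes.tsv", "w") as fh:
            fh.write("node\tp_value\tscore\n")
            for v in sorted(subnet.nodes):
                d = scored.graph.nodes[v]
                fh.write(f"{v}\t{d['p_value']:.6g}\t{d['score']:.6g}\n")
        ckio.write_sif(scored.graph.subgraph(subnet.nodes), out / "subnetwork.sif", "pp")
        ckio.write_json(
            {
                "lambda": fit.lambda_mix,
                "shape_a": fit.shape_a,
                "log_likelihood": fit.log_likelihood,
                "no_signal": fit.no_signal,
                "tau": scored.tau,
                "total_score": subnet.total_score,
                "method": subnet.method,
            },
            out / "subnetwork_fit.json",
        )
        summary["stages"].append("subnet")
        summary["subnetwork_size"] = len(subnet)
        summary["subnetwork_score"] = subnet.total_score
        summary["bum"] = {"lambda": fit.lambda_mix, "shape_a": fit.shape_a, "tau": scored.tau}
    else:
        summary["stages"].append("subnet:skipped")

    ckio.write_json(summary, out / "summary.json")
    logger.info("pipeline finished: %s", out / "summary.json")
    return summary
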