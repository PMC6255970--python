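"""Bundled reference tables from a published sorghum drought study.

Two small plain-TSV tables travel with the package:

* the cross-talk pathway table — 41 KEGG-style pathways with functional
  class, ``ko`` identifier and the number of candidate (drought-related)
  genes mapped to each;
* the GO enrichment table — enriched GO terms across the three ontologies
  (P/F/C) with overlap counts, background counts, raw p-values and printed
  FDRs.

They serve as fixed, printed inputs for filter-arithmetic and
BH-concordance checks; gene-level memberships are not part of them.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .pathways import PathwayDB, PathwayEntry

__all__ = [
    "drought_pathway_table",
    "drought_go_enrichment_table",
    "drought_pathway_db",
    "infer_bh_family_size",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("crosstalkkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def drought_pathway_table() -> pd.DataFrame:
    """Pathway name, functional class, ko id and candidate-gene count."""
    return _read("sorghum_drought_pathways.tsv")


def drought_go_enrichment_table() -> pd.DataFrame:
    """GO term enrichment results with printed p-values and FDRs."""
    return _read("sorghum_drought_go_enrichment.tsv")


def drought_pathway_db() -> PathwayDB:
    """The pathway table as a :class:`PathwayDB` with synthetic placeholder
    gene IDs sized to the printed per-pathway counts.

    The source publishes counts, not memberships, so member IDs here are
    synthetic fillers (``<pathway index>:g<i>``); the DB supports size-based
    filters only, not overlap analysis.
    """
    df = drought_pathway_table()
    entries = {}
    for idx, row in df.iterrows():
        genes = frozenset(f"p{idx:02d}:g{i:03d}" for i in range(int(row["n_genes"])))
        entries[row["pathway"]] = PathwayEntry(
            genes, row["functional_class"], row["ko"]
        )
    return PathwayDB(entries)


def infer_bh_family_size(p_values, fdr_values) -> int:
    """Family size implied by a printed BH column: ``round(FDR_1 / p_1)``
    at the smallest raw p-value (where the step-up minimum is inactive)."""
    import numpy as np

    p = np.asarray(p_values, dtype=float)
    q = np.asarray(fdr_values, dtype=float)
    i = int(np.argmin(p))
    return int(round(q[i] / p[i]))
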