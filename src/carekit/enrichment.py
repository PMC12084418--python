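"""Gene-set overlap enrichment and drug–gene interaction annotation.

Outlier gene lists are tested for over-representation in each set of a
collection (hypergeometric upper tail on the overlap, mirroring the MSigDB
overlap analysis), with Benjamini–Hochberg correction across the
collection.  The universe is the gene space the outliers were drawn from:
the filtered pan-cancer universe for pan-cancer outliers, the full gene
list for pan-disease outliers — the test's null must match the space the
query came from.  Druggability annotation is a case-insensitive join of
outlier genes against a source-filtered drug–gene interaction snapshot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import CareValidationError, DrugInteractionTable, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DruggabilityAnnotation",
    "overlap_enrichment",
    "annotate_drugs",
    "druggability_table",
]


@dataclass
class DruggabilityAnnotation:
    """Drug interactions for one gene; empty drug list when none are known."""

    gene: str
    drugs: list[tuple[str, str, str]] = field(default_factory=list)
    evidence_note: str = ""


def overlap_enrichment(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overlap enrichment of a gene list against a collection.

    For each set, with universe size M, m = |set ∩ universe|, query size N
    (after dropping query genes outside the universe, logged) and observed
    overlap x, the p-value is P[X >= x] for X ~ Hypergeom(M, m, N).  BH
    correction runs across all sets of the collection; rows are sorted by
    (p, set name).

    Returns columns ``set_name, universe_size, set_size, query_size,
    overlap, overlap_genes, p_value, fdr, significant``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise CareValidationError("empty universe for enrichment")
    query_all = {str(g).upper() for g in query}
    query_set = query_all & {str(g).upper() for g in universe_set}
    n_outside = len(query_all) - len(query_set)
    if n_outside:
        logger.info("dropping %d query genes outside the universe", n_outside)
    columns = [
        "set_name", "universe_size", "set_size", "query_size", "overlap",
        "overlap_genes", "p_value", "fdr", "significant",
    ]
    if not query_set:
        warnings.warn("empty enrichment query; no results", stacklevel=2)
        return pd.DataFrame(columns=columns)
    universe_upper = {str(g).upper() for g in universe_set}
    M, N = len(universe_upper), len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        members = {g for g in genes} & universe_upper
        m = len(members)
        overlap_genes = sorted(query_set & members)
        x = len(overlap_genes)
        p = float(hypergeom.sf(x - 1, M, m, N)) if m else 1.0
        rows.append((name, M, m, N, x, ";".join(overlap_genes), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=columns[:7])
    reject, fdr, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = reject
    return df.sort_values(["p_value", "set_name"], kind="stable").reset_index(
        drop=True
    )


def annotate_drugs(
    genes, table: DrugInteractionTable
) -> list[DruggabilityAnnotation]:
    """Join genes against the interaction table (case-insensitive).

    Every input gene gets an annotation; genes without any interaction get
    an empty drug list (present, not omitted).
    """
    by_gene = {
        g: sorted(
            zip(grp["drug"], grp["source"], grp["interaction_type"])
        )
        for g, grp in table.rows.groupby("gene")
    }
    out = []
    for gene in genes:
        key = str(gene).upper()
        out.append(DruggabilityAnnotation(gene=key, drugs=by_gene.get(key, [])))
    return out


def druggability_table(annotations: list[DruggabilityAnnotation]) -> pd.DataFrame:
    """TSV-ready long table: one row per (gene, drug) interaction."""
    rows = []
    for ann in annotations:
        if not ann.drugs:
            rows.append((ann.gene, "", "", ""))
        for drug, source, itype in ann.drugs:
            rows.append((ann.gene, drug, source, itype))
    return pd.DataFrame(rows, columns=["gene", "drug", "source", "interaction_type"])
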