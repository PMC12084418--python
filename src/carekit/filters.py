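"""Expression and variance gene filters defining the pan-cancer universe.

Two filters run in sequence on the comparator compendium (the focus sample
excluded).  The expression filter drops any gene where at least 80% of
samples have an expression of exactly 0.  The variance filter then sorts
the survivors by expression variance across the cohort and drops the 20%
with the lowest variance, regardless of absolute variance.  The pan-disease
analysis uses the full, unfiltered gene list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionCompendium

__all__ = [
    "FilteredGeneSet",
    "expression_filter",
    "variance_filter",
    "compute_filters",
    "select_universe",
    "filter_report",
]


@dataclass
class FilteredGeneSet:
    """Outcome of the two-stage gene filtering, with per-gene drop reasons."""

    retained: list[str]
    dropped_expression: list[str]
    dropped_variance: list[str]
    zero_fraction: pd.Series  # per input gene
    variance: pd.Series  # per expression-filter survivor

    def validate(self, input_genes) -> "FilteredGeneSet":
        parts = [self.retained, self.dropped_expression, self.dropped_variance]
        union = set().union(*map(set, parts))
        if union != set(input_genes) or sum(map(len, parts)) != len(input_genes):
            raise ValueError("filter partition does not tile the input gene list")
        n_surv = len(input_genes) - len(self.dropped_expression)
        if len(self.dropped_variance) != math.floor(0.2 * n_surv):
            raise ValueError("variance-filter dropped count violates the floor rule")
        return self


def expression_filter(
    compendium: ExpressionCompendium, zero_threshold: float = 0.80
) -> tuple[list[str], list[str], pd.Series]:
    """Drop genes whose fraction of exact-zero values is >= ``zero_threshold``.

    The boundary is inclusive: a gene zero in exactly 80% of samples is
    dropped.  Returns (kept genes, dropped genes, per-gene zero fraction),
    both lists in input order.
    """
    zero_fraction = (compendium.values == 0).mean(axis=1)
    dropped_mask = zero_fraction >= zero_threshold
    kept = compendium.genes[~dropped_mask].tolist()
    dropped = compendium.genes[dropped_mask].tolist()
    return kept, dropped, zero_fraction


def variance_filter(
    values: pd.DataFrame, drop_fraction: float = 0.20
) -> tuple[list[str], list[str], pd.Series]:
    """Drop the ``drop_fraction`` of genes with the lowest expression variance.

    ``values`` is the matrix restricted to expression-filter survivors.
    Exactly floor(drop_fraction * n) genes are dropped.  Variance is the
    population variance (ddof=0); ties are broken by gene symbol so that
    the cut is deterministic.
    """
    variance = values.var(axis=1, ddof=0)
    order = variance.sort_index().sort_values(kind="stable")
    n_drop = math.floor(drop_fraction * len(order))
    dropped = set(order.index[:n_drop])
    kept = [g for g in values.index if g not in dropped]
    dropped_list = [g for g in values.index if g in dropped]
    return kept, dropped_list, variance


def compute_filters(
    compendium: ExpressionCompendium,
    zero_threshold: float = 0.80,
    drop_fraction: float = 0.20,
) -> FilteredGeneSet:
    """Run both filters in sequence and return the full partition."""
    kept_e, dropped_e, zero_fraction = expression_filter(compendium, zero_threshold)
    kept_v, dropped_v, variance = variance_filter(
        compendium.values.loc[kept_e], drop_fraction
    )
    return FilteredGeneSet(
        retained=kept_v,
        dropped_expression=dropped_e,
        dropped_variance=dropped_v,
        zero_fraction=zero_fraction,
        variance=variance,
    ).validate(compendium.genes)


def select_universe(
    compendium: ExpressionCompendium,
    analysis_kind: str,
    filtered: FilteredGeneSet | None = None,
) -> list[str]:
    """The gene universe for an analysis: filtered for pan-cancer, full for
    pan-disease."""
    if analysis_kind == "pan_disease":
        return compendium.genes.tolist()
    if analysis_kind == "pan_cancer":
        if filtered is None:
            filtered = compute_filters(compendium)
        return list(filtered.retained)
    raise ValueError(f"unknown analysis kind {analysis_kind!r}")


def filter_report(filtered: FilteredGeneSet) -> pd.DataFrame:
    """Per-gene TSV-ready report: zero fraction, variance and filter status."""
    status = pd.Series("kept", index=filtered.zero_fraction.index)
    status.loc[filtered.dropped_expression] = "dropped_expression"
    status.loc[filtered.dropped_variance] = "dropped_variance"
    return pd.DataFrame(
        {
            "zero_fraction": filtered.zero_fraction,
            "variance": filtered.variance.reindex(filtered.zero_fraction.index),
            "status": status,
        }
    ).rename_axis("gene")
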