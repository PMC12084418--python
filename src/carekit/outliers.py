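"""Comparator cohort assembly and Tukey overexpression outlier calling.

A focus sample is compared against the pan-cancer cohort (the whole
compendium) and four personalized pan-disease cohorts: (1) samples with the
same diagnosis, (2) first-degree molecular neighbors, (3) first- and
second-degree neighbors, (4) all samples of the diseases present among the
top-6 most correlated samples.  Per cohort and gene, the overexpression
threshold is Tukey's upper fence, Q75 + 1.5 * (Q75 - Q25), of the gene's
expression across the cohort; the focus expression must strictly exceed it
(and pass an absolute expression floor) to be called an outlier.  A gene is
a pan-disease outlier when it exceeds the threshold in at least two of the
four cohorts; when the cohorts collapse into fewer than two distinct usable
sets (the rare-disease situation), a single merged cohort is used and the
rule degrades to 1-of-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CareValidationError, ExpressionCompendium, FocusSample
from .similarity import SimilarityResult

logger = logging.getLogger(__name__)

__all__ = [
    "PAN_DISEASE_KINDS",
    "CohortSpec",
    "build_cohorts",
    "usable_pan_disease_cohorts",
    "tukey_threshold",
    "call_outliers",
    "pan_disease_aggregate",
    "neighbor_label_concordance",
    "cohort_table",
]

#: The four personalized pan-disease cohort kinds, in reporting order.
PAN_DISEASE_KINDS = (
    "same_diagnosis",
    "first_degree",
    "first_and_second_degree",
    "top6_diseases",
)


@dataclass
class CohortSpec:
    """A named comparator cohort: a set of compendium sample ids."""

    kind: str
    members: list[str]
    usable: bool
    reason_unusable: str = ""

    def __len__(self) -> int:
        return len(self.members)


def build_cohorts(
    focus: FocusSample,
    compendium: ExpressionCompendium,
    similarity: SimilarityResult,
    min_cohort_size: int = 20,
) -> list[CohortSpec]:
    """Assemble the four personalized pan-disease cohorts.

    Each cohort is marked usable iff it has at least ``min_cohort_size``
    members (quartiles of tiny cohorts are unstable).  If fewer than two
    *distinct* usable cohorts remain — distinct meaning differing by at
    least one member — a single ``merged_pan_disease`` cohort equal to the
    deduplicated union of all four is appended, and downstream aggregation
    degrades to a 1-of-1 rule.
    """
    diseases = compendium.disease_labels()
    same_dx = diseases.index[diseases == focus.diagnosis].tolist()
    first = list(similarity.first_degree)
    first_second = first + list(similarity.second_degree)
    top_diseases = set(diseases.loc[similarity.top_k_samples])
    top6 = diseases.index[diseases.isin(top_diseases)].tolist()

    def spec(kind: str, members: list[str]) -> CohortSpec:
        members = [m for m in members if m != focus.sample_id]
        usable = len(members) >= min_cohort_size
        reason = "" if usable else (
            f"{len(members)} members < min_cohort_size={min_cohort_size}"
        )
        return CohortSpec(kind, members, usable, reason)

    cohorts = [
        spec("same_diagnosis", same_dx),
        spec("first_degree", first),
        spec("first_and_second_degree", first_second),
        spec("top6_diseases", top6),
    ]

    distinct_usable = {frozenset(c.members) for c in cohorts if c.usable}
    if len(distinct_usable) <= 1:
        union = sorted(set().union(*(c.members for c in cohorts)))
        merged = spec("merged_pan_disease", union)
        logger.info(
            "pan-disease cohorts collapsed (%d distinct usable); "
            "falling back to a single merged cohort of %d samples",
            len(distinct_usable), len(merged),
        )
        cohorts.append(merged)
    return cohorts


def usable_pan_disease_cohorts(cohorts: list[CohortSpec]) -> list[CohortSpec]:
    """The cohorts that actually feed pan-disease calling: the merged cohort
    alone when the fallback triggered, otherwise the usable ones."""
    merged = [c for c in cohorts if c.kind == "merged_pan_disease"]
    if merged:
        return [c for c in merged if c.usable]
    return [c for c in cohorts if c.usable]


def tukey_threshold(cohort_values) -> tuple[float, float, float, float]:
    """Tukey's upper fence for one gene across a cohort.

    Quartiles use linear interpolation between order statistics; the
    threshold is Q75 + 1.5 * IQR.  Returns (q25, q75, iqr, threshold).
    """
    vals = np.asarray(cohort_values, float)
    if vals.size == 0:
        raise CareValidationError("empty cohort")
    q25, q75 = np.quantile(vals, [0.25, 0.75])
    iqr = q75 - q25
    return float(q25), float(q75), float(iqr), float(q75 + 1.5 * iqr)


def call_outliers(
    focus: FocusSample,
    cohort: CohortSpec,
    compendium: ExpressionCompendium,
    gene_universe,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Call per-gene overexpression outliers against one cohort.

    Returns one row per universe gene with columns ``gene, cohort_kind,
    q25, q75, iqr, threshold, focus_expression, is_outlier``.  The call is
    strict: focus expression must exceed the threshold, and must be at
    least ``expression_floor`` log2(TPM+1) (default 1.0, i.e. ~1 TPM —
    genes below that are not clinically reportable however extreme;
    set 0 to disable).
    """
    if not cohort.usable:
        raise CareValidationError(
            f"cohort {cohort.kind!r} is not usable: {cohort.reason_unusable}"
        )
    genes = list(gene_universe)
    sub = compendium.values.loc[genes, cohort.members].to_numpy()
    q25, q75 = np.quantile(sub, [0.25, 0.75], axis=1)
    iqr = q75 - q25
    threshold = q75 + 1.5 * iqr
    focus_expr = focus.expression.loc[genes].to_numpy()
    is_outlier = (focus_expr > threshold) & (focus_expr >= expression_floor)
    return pd.DataFrame(
        {
            "gene": genes,
            "cohort_kind": cohort.kind,
            "q25": q25,
            "q75": q75,
            "iqr": iqr,
            "threshold": threshold,
            "focus_expression": focus_expr,
            "is_outlier": is_outlier,
        }
    )


def pan_disease_aggregate(calls_by_cohort: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-cohort calls into the pan-disease outlier list.

    A gene is flagged when it is an outlier in at least min(2, n_usable)
    of the usable cohorts; with a single merged cohort this is the 1-of-1
    rule.  Returns columns ``gene, n_cohorts_usable, n_cohorts_outlier,
    is_pan_disease_outlier``.
    """
    if not calls_by_cohort:
        warnings.warn("no usable pan-disease cohort; empty outlier list",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["gene", "n_cohorts_usable", "n_cohorts_outlier",
                     "is_pan_disease_outlier"]
        )
    n_usable = len(calls_by_cohort)
    required = min(2, n_usable)
    counts: pd.Series | None = None
    for calls in calls_by_cohort.values():
        c = calls.set_index("gene")["is_outlier"].astype(int)
        counts = c if counts is None else counts.add(c, fill_value=0)
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "n_cohorts_usable": n_usable,
            "n_cohorts_outlier": counts.to_numpy(dtype=int),
        }
    )
    out["is_pan_disease_outlier"] = out["n_cohorts_outlier"] >= required
    return out.reset_index(drop=True)


def neighbor_label_concordance(
    compendium: ExpressionCompendium,
    pairwise: pd.DataFrame,
    k: int = 5,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag samples whose nearest neighbors disagree with their disease label.

    An automated stand-in for the manual review of the most-similar-samples
    table used to spot batch effects and mislabelled samples.  For each
    sample, the fraction of its k nearest neighbors (by pairwise Spearman
    rho) sharing its disease label is computed; samples below
    ``min_fraction`` are flagged for review, never excluded automatically.
    A sample whose disease has fewer than k other members is exempt (its
    neighborhood cannot be label-concordant even in a perfect embedding)
    and the exemption is logged.
    """
    diseases = compendium.disease_labels()
    counts = diseases.value_counts()
    rows = []
    rho = pairwise.to_numpy().copy()
    np.fill_diagonal(rho, -np.inf)
    samples = list(pairwise.index)
    for i, s in enumerate(samples):
        own = diseases[s]
        exempt = counts[own] - 1 < k
        order = np.argsort(-rho[i], kind="stable")[:k]
        nn = [samples[j] for j in order]
        frac = float(np.mean([diseases[t] == own for t in nn])) if nn else 0.0
        flagged = (not exempt) and frac < min_fraction
        if exempt:
            logger.info("sample %s exempt from concordance flagging "
                        "(disease %r has < %d other members)", s, own, k)
        rows.append((s, own, frac, exempt, flagged))
    return pd.DataFrame(
        rows, columns=["sample_id", "disease", "concordance", "exempt", "flagged"]
    )


def cohort_table(cohorts: list[CohortSpec]) -> pd.DataFrame:
    """TSV-ready summary of the assembled cohorts."""
    return pd.DataFrame(
        [
            {
                "kind": c.kind,
                "size": len(c),
                "usable": c.usable,
                "reason_unusable": c.reason_unusable,
            }
            for c in cohorts
        ]
    )
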