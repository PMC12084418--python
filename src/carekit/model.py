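"""The CARE model: orchestration of the full comparative-expression analysis.

`CareModel` is built from a compendium, a focus sample and optional
annotation resources; :meth:`CareModel.fit` runs the stages in order —
gene filters → molecular similarity → cohort assembly → pan-cancer and
pan-disease Tukey outlier calling → gene-set enrichment → druggability —
and returns a :class:`CareResults` carrying every table, the degradations
that occurred (merged cohort, subsampled percentile pool, skipped QC) and
a provenance block.  The run is deterministic given inputs, configuration
and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .io import (
    CareValidationError,
    DrugInteractionTable,
    ExpressionCompendium,
    FocusSample,
    GeneSetCollection,
    align_focus,
)
from .filters import FilteredGeneSet, compute_filters, filter_report, select_universe
from .similarity import SimilarityResult, compute_similarity, similarity_report
from .outliers import (
    CohortSpec,
    build_cohorts,
    call_outliers,
    cohort_table,
    neighbor_label_concordance,
    pan_disease_aggregate,
    usable_pan_disease_cohorts,
)
from .enrichment import annotate_drugs, druggability_table, overlap_enrichment
from .qc import QcVerdict

__all__ = ["CareConfig", "CareModel", "CareResults", "extract_focus"]


@dataclass
class CareConfig:
    """Tunable parameters of a CARE run.

    min_cohort_size : smallest cohort whose quartiles are trusted (samples).
    expression_floor : minimum focus expression, log2(TPM+1), for a
        reportable outlier; 0 disables.
    top_k : number of most-correlated samples whose diseases define the
        top-diseases cohort.
    percentile : quantile of the pairwise-rho pool defining molecular
        similarity.
    max_pairs : optional cap on the percentile pool (seeded subsample).
    zero_threshold / variance_drop_fraction : the two gene-filter knobs.
    alpha : BH significance level for enrichment.
    strength_labels : free-text analytical-strength label per gene, echoed
        verbatim into the actionable-findings table (never computed).
    """

    min_cohort_size: int = 20
    expression_floor: float = 1.0
    top_k: int = 6
    percentile: float = 0.95
    max_pairs: int | None = None
    zero_threshold: float = 0.80
    variance_drop_fraction: float = 0.20
    alpha: float = 0.05
    concordance_k: int = 5
    concordance_min_fraction: float = 0.5
    strength_labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def extract_focus(
    compendium: ExpressionCompendium, sample_id: str, diagnosis: str | None = None
) -> tuple[ExpressionCompendium, FocusSample]:
    """Pull one column out of the compendium as the focus sample.

    The returned compendium no longer contains the column (the focus never
    sits inside its own comparator cohorts).  The diagnosis defaults to the
    sample's metadata disease label.
    """
    if sample_id not in compendium.samples:
        raise CareValidationError(f"focus sample {sample_id!r} not in compendium")
    if diagnosis is None:
        if compendium.metadata is None or sample_id not in compendium.metadata.index:
            raise CareValidationError(
                f"no diagnosis given and no metadata for {sample_id!r}"
            )
        diagnosis = str(compendium.metadata.loc[sample_id, "disease"])
    focus = FocusSample(
        sample_id=sample_id,
        expression=compendium.values[sample_id].copy(),
        diagnosis=diagnosis,
    ).validate()
    return compendium.drop_samples([sample_id]), focus


@dataclass
class CareResults:
    """Everything a CARE run produced, with summary and report accessors."""

    focus_id: str
    diagnosis: str
    config: CareConfig
    filtered: FilteredGeneSet
    similarity: SimilarityResult
    cohorts: list[CohortSpec]
    pan_cancer_calls: pd.DataFrame
    pan_disease_calls: dict[str, pd.DataFrame]
    pan_disease_summary: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]
    druggability: pd.DataFrame
    concordance: pd.DataFrame
    qc: QcVerdict | None
    degradations: list[str]
    provenance: dict

    @property
    def pan_cancer_outliers(self) -> list[str]:
        calls = self.pan_cancer_calls
        return calls.loc[calls["is_outlier"], "gene"].tolist()

    @property
    def pan_disease_outliers(self) -> list[str]:
        s = self.pan_disease_summary
        if s.empty:
            return []
        return s.loc[s["is_pan_disease_outlier"], "gene"].tolist()

    @property
    def outlier_genes(self) -> list[str]:
        return sorted(set(self.pan_cancer_outliers) | set(self.pan_disease_outliers))

    def actionable_findings(self) -> pd.DataFrame:
        """Outlier genes with at least one drug interaction, with the
        configured free-text strength label echoed per gene."""
        drugs = self.druggability
        hits = drugs[(drugs["gene"].isin(self.outlier_genes)) & (drugs["drug"] != "")]
        out = hits.copy()
        out["strength"] = out["gene"].map(self.config.strength_labels).fillna("")
        return out.reset_index(drop=True)

    def summary(self) -> str:
        """One-page text summary of the run."""
        lines = [
            "CARE analysis summary",
            "=" * 60,
            f"focus sample   : {self.focus_id} ({self.diagnosis})",
            f"gene universe  : {len(self.filtered.zero_fraction)} input, "
            f"{len(self.filtered.retained)} after filters "
            f"({len(self.filtered.dropped_expression)} expression-dropped, "
            f"{len(self.filtered.dropped_variance)} variance-dropped)",
            f"neighbor rho > : {self.similarity.neighbor_threshold:.4f} "
            f"(95th pct of pairwise Spearman)",
            f"neighbors      : {len(self.similarity.first_degree)} first-degree, "
            f"{len(self.similarity.second_degree)} second-degree",
        ]
        if self.qc is not None:
            lines.append(
                f"QC             : {self.qc.mend_reads:,} MEND / "
                f"{self.qc.total_reads:,} reads -> "
                f"{'PASS' if self.qc.passed else 'FAIL'}"
            )
        lines.append("cohorts:")
        for c in self.cohorts:
            flag = "usable" if c.usable else f"UNUSABLE ({c.reason_unusable})"
            lines.append(f"  {c.kind:<26s} n={len(c):<6d} {flag}")
        lines.append(
            f"pan-cancer outliers  : {len(self.pan_cancer_outliers)}"
        )
        lines.append(
            f"pan-disease outliers : {len(self.pan_disease_outliers)}"
        )
        findings = self.actionable_findings()
        lines.append(f"actionable findings  : {len(findings)} gene-drug pairs")
        for _, row in findings.head(12).iterrows():
            lab = f"  [{row['strength']}]" if row["strength"] else ""
            lines.append(f"  {row['gene']:<10s} {row['drug']}{lab}")
        for d in self.degradations:
            lines.append(f"note: {d}")
        return "\n".join(lines)

    def tables(self) -> dict[str, pd.DataFrame]:
        """All TSV-ready tables keyed by report file stem."""
        out = {
            "cohorts": cohort_table(self.cohorts),
            "outliers_pan_cancer": self.pan_cancer_calls,
            "outliers_pan_disease": self.pan_disease_summary,
            "drugs": self.druggability,
            "concordance": self.concordance,
            "filter_report": filter_report(self.filtered),
            "similarity": self._similarity_table,
        }
        for name, df in self.enrichment.items():
            out[f"enrichment_{name}"] = df
        return out

    _similarity_table: pd.DataFrame = field(default=None, repr=False)


class CareModel:
    """Comparative Analysis of RNA Expression for one focus tumor sample.

    Parameters
    ----------
    compendium : ExpressionCompendium
        The comparator compendium (metadata attached; must not contain the
        focus sample — use :func:`extract_focus` to pull it out).
    focus : FocusSample
        The patient expression profile; aligned to the compendium genes.
    gene_sets : dict of collection label -> GeneSetCollection, optional
        Collections for overlap enrichment of the outlier lists.
    drug_table : DrugInteractionTable, optional
        Source-filtered drug–gene interaction snapshot.
    qc : QcVerdict, optional
        Read-level QC verdict, echoed into the report (None = QC skipped).
    config : CareConfig
    """

    def __init__(
        self,
        compendium: ExpressionCompendium,
        focus: FocusSample,
        gene_sets: dict[str, GeneSetCollection] | None = None,
        drug_table: DrugInteractionTable | None = None,
        qc: QcVerdict | None = None,
        config: CareConfig | None = None,
        input_digests: dict[str, str] | None = None,
    ):
        self.config = config or CareConfig()
        compendium.validate()
        if focus.sample_id in set(compendium.samples):
            warnings.warn(
                f"focus sample {focus.sample_id!r} found in compendium; "
                "removing it from the comparator matrix",
                stacklevel=2,
            )
            compendium = compendium.drop_samples([focus.sample_id])
        self.compendium = compendium
        self.focus = align_focus(compendium, focus)
        self.gene_sets = gene_sets or {}
        self.drug_table = drug_table
        self.qc = qc
        self.input_digests = input_digests or {}

    def fit(self) -> CareResults:
        cfg = self.config
        degradations: list[str] = []

        filtered = compute_filters(
            self.compendium, cfg.zero_threshold, cfg.variance_drop_fraction
        )
        pan_cancer_universe = select_universe(self.compendium, "pan_cancer", filtered)
        pan_disease_universe = select_universe(self.compendium, "pan_disease")

        sim = compute_similarity(
            self.focus,
            self.compendium,
            gene_subset=pan_cancer_universe,
            percentile=cfg.percentile,
            k=cfg.top_k,
            max_pairs=cfg.max_pairs,
            seed=cfg.seed,
        )
        if sim.subsampled:
            degradations.append(
                f"pairwise percentile pool subsampled to {cfg.max_pairs} pairs"
            )

        cohorts = build_cohorts(self.focus, self.compendium, sim, cfg.min_cohort_size)
        if any(c.kind == "merged_pan_disease" for c in cohorts):
            degradations.append(
                "pan-disease cohorts collapsed; single merged cohort used (1-of-1 rule)"
            )

        pan_cancer_cohort = CohortSpec(
            kind="pan_cancer",
            members=[s for s in self.compendium.samples],
            usable=self.compendium.n_samples >= cfg.min_cohort_size,
            reason_unusable=""
            if self.compendium.n_samples >= cfg.min_cohort_size
            else "compendium smaller than min_cohort_size",
        )
        if not pan_cancer_cohort.usable:
            raise CareValidationError(
                "compendium too small for pan-cancer analysis"
            )
        pan_cancer_calls = call_outliers(
            self.focus, pan_cancer_cohort, self.compendium,
            pan_cancer_universe, cfg.expression_floor,
        )

        usable = usable_pan_disease_cohorts(cohorts)
        if not usable:
            degradations.append(
                "no usable pan-disease cohort; analysis degrades to pan-cancer only"
            )
            warnings.warn(degradations[-1], stacklevel=2)
        pan_disease_calls = {
            c.kind: call_outliers(
                self.focus, c, self.compendium,
                pan_disease_universe, cfg.expression_floor,
            )
            for c in usable
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pan_disease_summary = pan_disease_aggregate(pan_disease_calls)

        pc_out = pan_cancer_calls.loc[pan_cancer_calls["is_outlier"], "gene"]
        pd_out = (
            pan_disease_summary.loc[
                pan_disease_summary.get("is_pan_disease_outlier", pd.Series(dtype=bool))
                == True,  # noqa: E712
                "gene",
            ]
            if not pan_disease_summary.empty
            else pd.Series(dtype=object)
        )
        enrichment: dict[str, pd.DataFrame] = {}
        for label, collection in self.gene_sets.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enrichment[f"pan_cancer_{label}"] = overlap_enrichment(
                    pc_out, collection, pan_cancer_universe, cfg.alpha
                )
                enrichment[f"pan_disease_{label}"] = overlap_enrichment(
                    pd_out, collection, pan_disease_universe, cfg.alpha
                )

        all_outliers = sorted(set(pc_out) | set(pd_out))
        if self.drug_table is not None:
            druggability = druggability_table(
                annotate_drugs(all_outliers, self.drug_table)
            )
        else:
            druggability = pd.DataFrame(
                columns=["gene", "drug", "source", "interaction_type"]
            )

        concordance = neighbor_label_concordance(
            self.compendium, sim.pairwise,
            cfg.concordance_k, cfg.concordance_min_fraction,
        )
        if self.qc is None:
            degradations.append("read-level QC skipped (no read flags supplied)")

        provenance = {
            "software": "carekit",
            "version": __version__,
            "schema_version": "1.0",
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_digest": cfg.digest(),
            "input_digests": dict(self.input_digests),
            "n_compendium_samples": int(self.compendium.n_samples),
            "n_genes": int(self.compendium.n_genes),
            "degradations": list(degradations),
        }

        results = CareResults(
            focus_id=self.focus.sample_id,
            diagnosis=self.focus.diagnosis,
            config=cfg,
            filtered=filtered,
            similarity=sim,
            cohorts=cohorts,
            pan_cancer_calls=pan_cancer_calls,
            pan_disease_calls=pan_disease_calls,
            pan_disease_summary=pan_disease_summary,
            enrichment=enrichment,
            druggability=druggability,
            concordance=concordance,
            qc=self.qc,
            degradations=degradations,
            provenance=provenance,
        )
        results._similarity_table = similarity_report(sim, self.compendium)
        return results
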