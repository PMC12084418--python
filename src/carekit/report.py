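"""Assembly and serialization of the CARE report.

A finished run is written as ``report.json`` (machine-readable, versioned
schema), one TSV per table, and a one-page ``summary.txt``.  The module
also handles comparator-cohort composition tables (per-disease sample
counts), including the packaged reference composition of a 339-sample
merged pan-disease cohort from a rare-disease analysis.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import CareParseError, CareValidationError, ExpressionCompendium
from .outliers import CohortSpec

__all__ = [
    "build_report",
    "write_report",
    "validate_report",
    "load_cohort_composition",
    "composition_total",
    "cohort_disease_composition",
]

REPORT_REQUIRED_KEYS = {
    "schema_version": str,
    "focus": dict,
    "qc": (dict, type(None)),
    "cohorts": list,
    "similarity": dict,
    "pan_cancer_outliers": list,
    "pan_disease_outliers": list,
    "enrichment": dict,
    "druggability": list,
    "actionable_findings": list,
    "provenance": dict,
}


def build_report(results) -> dict:
    """Assemble the machine-readable report dict from a CareResults."""
    sim_table = results._similarity_table.reset_index()
    report = {
        "schema_version": results.provenance["schema_version"],
        "focus": {"sample_id": results.focus_id, "diagnosis": results.diagnosis},
        "qc": results.qc.to_dict() if results.qc is not None else None,
        "cohorts": [
            {
                "kind": c.kind,
                "size": len(c),
                "usable": c.usable,
                "reason_unusable": c.reason_unusable,
            }
            for c in results.cohorts
        ],
        "similarity": {
            "neighbor_threshold": results.similarity.neighbor_threshold,
            "n_first_degree": len(results.similarity.first_degree),
            "n_second_degree": len(results.similarity.second_degree),
            "top_samples": sim_table.head(results.config.top_k)[
                ["sample_id", "disease", "rho"]
            ].to_dict(orient="records"),
        },
        "pan_cancer_outliers": results.pan_cancer_outliers,
        "pan_disease_outliers": results.pan_disease_outliers,
        "enrichment": {
            name: df.to_dict(orient="records")
            for name, df in results.enrichment.items()
        },
        "druggability": results.druggability.to_dict(orient="records"),
        "actionable_findings": results.actionable_findings().to_dict(
            orient="records"
        ),
        "provenance": results.provenance,
    }
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Check the report against the required-keys schema; raise on violation."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise CareValidationError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise CareValidationError(
                f"report key {key!r} has type {type(report[key]).__name__}"
            )
    for finding in report["actionable_findings"]:
        gene = finding["gene"]
        if (
            gene not in report["pan_cancer_outliers"]
            and gene not in report["pan_disease_outliers"]
        ):
            raise CareValidationError(
                f"actionable finding {gene!r} is in no outlier list"
            )
    prov = report["provenance"]
    for key in ("seed", "config_digest", "version", "degradations"):
        if key not in prov:
            raise CareValidationError(f"provenance missing {key!r}")


def write_report(results, out_dir) -> dict[str, Path]:
    """Write report.json, per-table TSVs and summary.txt; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = build_report(results)
    paths: dict[str, Path] = {}

    paths["report"] = out / "report.json"
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    for name, df in results.tables().items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=df.index.name is not None)
        paths[name] = p

    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(results.summary() + "\n", encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Cohort composition tables


def load_cohort_composition(path=None) -> pd.DataFrame:
    """Load a per-disease cohort composition table (columns disease, n).

    With no path, loads the packaged reference composition: the 34-disease
    breakdown of the merged pan-disease comparator cohort assembled for a
    rare-disease (myoepithelial carcinoma) analysis against a public
    pan-cancer compendium.
    """
    if path is None:
        ref = resources.files("carekit").joinpath(
            "data/merged_cohort_composition.tsv"
        )
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"disease", "n"} <= set(df.columns):
        raise CareParseError("composition table needs columns 'disease' and 'n'")
    if (df["n"] < 1).any():
        raise CareValidationError("composition counts must be >= 1")
    return df


def composition_total(composition: pd.DataFrame) -> int:
    """Total cohort size implied by a per-disease composition table."""
    return int(composition["n"].sum())


def cohort_disease_composition(
    cohort: CohortSpec, compendium: ExpressionCompendium
) -> pd.DataFrame:
    """Per-disease sample counts of an assembled cohort, largest first."""
    diseases = compendium.disease_labels().loc[cohort.members]
    counts = diseases.value_counts()
    return (
        counts.rename("n")
        .rename_axis("disease")
        .reset_index()
        .sort_values(["n", "disease"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
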