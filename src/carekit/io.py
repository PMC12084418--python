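"""Readers, writers and validated domain containers for CARE inputs.

Four external formats feed the pipeline: a gene × sample expression matrix
in log2(TPM+1) units (TSV), a per-sample clinical table carrying disease
labels (TSV), gene-set collections (GMT), and a drug–gene interaction
snapshot (TSV).  Everything is validated into the in-memory containers
defined here before any analysis runs.

Conventions: TSV is the canonical dialect (tab-separated, UTF-8); gene
identity is by symbol, case-folded to upper; the expression matrix must be
dense and non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CareError",
    "CareParseError",
    "CareValidationError",
    "ExpressionCompendium",
    "FocusSample",
    "GeneSetCollection",
    "DrugInteractionTable",
    "DGIDB_CANCER_SOURCES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_drug_table",
    "write_drug_table",
    "align_focus",
]

#: The four curated DGIdb source databases with known cancer relevance that
#: interaction tables are restricted to by default.
DGIDB_CANCER_SOURCES = (
    "CIViC",
    "Cancer Commons",
    "My Cancer Genome",
    "My Cancer Genome Clinical Trial",
)


class CareError(Exception):
    """Base class for all carekit errors."""


class CareParseError(CareError, ValueError):
    """A file could not be parsed into the expected structure."""


class CareValidationError(CareError, ValueError):
    """Parsed data violates a pipeline invariant."""


def _fold_genes(genes) -> pd.Index:
    return pd.Index([str(g).strip().upper() for g in genes], name="gene")


@dataclass
class ExpressionCompendium:
    """A gene × sample matrix of log2(TPM+1) values plus sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = upper-cased gene symbols), samples in
        columns.  Dense, non-negative.
    metadata : pandas.DataFrame or None
        Indexed by sample id with at least a ``disease`` column.  May be
        absent immediately after reading the matrix; every analysis entry
        point requires it.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def disease_labels(self) -> pd.Series:
        """Disease label per sample, aligned to the matrix column order."""
        if self.metadata is None:
            raise CareValidationError("compendium has no sample metadata attached")
        return self.metadata.loc[self.samples, "disease"]

    def validate(self, require_metadata: bool = True) -> "ExpressionCompendium":
        """Check the container invariants; return self for chaining."""
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise CareValidationError(f"duplicate gene symbols: {dups[:10]}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise CareValidationError(f"duplicate sample identifiers: {dups[:10]}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CareParseError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            raise CareValidationError("expression matrix contains missing values")
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise CareValidationError(
                f"negative expression at gene {vals.index[gi]!r}, "
                f"sample {vals.columns[si]!r}: log2(TPM+1) must be >= 0"
            )
        if require_metadata:
            if self.metadata is None:
                raise CareValidationError("sample metadata required but absent")
            missing = self.samples.difference(self.metadata.index)
            if len(missing):
                raise CareValidationError(
                    f"samples without metadata record: {list(missing[:10])}"
                )
            disease = self.metadata.loc[self.samples, "disease"]
            empty = disease.index[
                disease.isna() | (disease.astype(str).str.strip() == "")
            ]
            if len(empty):
                raise CareValidationError(
                    f"samples with empty disease label: {list(empty[:10])}"
                )
        return self

    def attach_metadata(self, metadata: pd.DataFrame) -> "ExpressionCompendium":
        """Join clinical metadata; extra metadata samples warn, missing error."""
        extra = metadata.index.difference(self.samples)
        if len(extra):
            warnings.warn(
                f"{len(extra)} metadata samples absent from the expression "
                f"matrix (retained in metadata): {list(extra[:5])}",
                stacklevel=2,
            )
        out = ExpressionCompendium(values=self.values, metadata=metadata)
        return out.validate(require_metadata=True)

    def drop_samples(self, sample_ids) -> "ExpressionCompendium":
        keep = [s for s in self.samples if s not in set(sample_ids)]
        meta = self.metadata.loc[keep] if self.metadata is not None else None
        return ExpressionCompendium(self.values[keep], meta)


@dataclass
class FocusSample:
    """The patient (focus) expression profile to be compared to a compendium."""

    sample_id: str
    expression: pd.Series  # indexed by upper-cased gene symbol, log2(TPM+1)
    diagnosis: str

    def validate(self) -> "FocusSample":
        vals = self.expression.to_numpy()
        if self.expression.index.has_duplicates:
            raise CareValidationError("duplicate gene symbols in focus expression")
        if np.isnan(vals).any():
            raise CareValidationError("focus expression contains missing values")
        if (vals < 0).any():
            raise CareValidationError("focus expression must be >= 0 (log2(TPM+1))")
        if not str(self.diagnosis).strip():
            raise CareValidationError("focus sample has an empty diagnosis")
        return self


def align_focus(compendium: ExpressionCompendium, focus: FocusSample) -> FocusSample:
    """Align a focus expression vector onto the compendium's gene list.

    Symbols are joined after upper-casing; genes present in the compendium
    but absent from the focus vector are an error, while focus-only genes
    are dropped with a logged count.
    """
    expr = focus.expression.copy()
    expr.index = _fold_genes(expr.index)
    missing = compendium.genes.difference(expr.index)
    if len(missing):
        raise CareValidationError(
            f"focus sample lacks {len(missing)} compendium genes "
            f"(e.g. {list(missing[:5])})"
        )
    dropped = expr.index.difference(compendium.genes)
    if len(dropped):
        logger.info(
            "dropping %d focus genes absent from the compendium", len(dropped)
        )
    aligned = expr.loc[compendium.genes]
    return FocusSample(focus.sample_id, aligned, focus.diagnosis).validate()


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB Hallmark or Canonical Pathways)."""

    sets: dict[str, list[str]]
    source_label: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def validate(self) -> "GeneSetCollection":
        for name, genes in self.sets.items():
            if not genes:
                raise CareValidationError(f"gene set {name!r} is empty")
        return self


@dataclass
class DrugInteractionTable:
    """Rows of (gene, drug, source, interaction_type), source-filtered."""

    rows: pd.DataFrame  # columns: gene, drug, source, interaction_type
    allowed_sources: tuple[str, ...] = DGIDB_CANCER_SOURCES

    def __len__(self) -> int:
        return len(self.rows)

    def genes(self) -> set[str]:
        return set(self.rows["gene"])


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_matrix(
    path, orientation: str = "genes_in_rows"
) -> ExpressionCompendium:
    """Read a TSV expression matrix into a compendium (metadata not attached).

    Parameters
    ----------
    path : path-like
        TSV with one identifier header row and one identifier column.
    orientation : {"genes_in_rows", "samples_in_rows"}
        Layout of the file; the returned matrix is always genes × samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise CareParseError(
            f"non-numeric cell at row {row!r}, column {col!r} in {path}"
        )
    if orientation == "samples_in_rows":
        df = df.T
    df.index = _fold_genes(df.index)
    df.columns = [str(c) for c in df.columns]
    df = df.astype(float)
    return ExpressionCompendium(values=df).validate(require_metadata=False)


def write_expression_matrix(
    compendium: ExpressionCompendium, path, orientation: str = "genes_in_rows"
) -> None:
    """Write the matrix as TSV at full float precision (round-trip safe)."""
    df = compendium.values
    if orientation == "samples_in_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table: columns ``sample_id``, ``disease``, extras kept.

    Returns a DataFrame indexed by sample_id.  Empty disease labels are an
    error listing the offending samples; the join against the matrix is the
    caller's job (see :meth:`ExpressionCompendium.attach_metadata`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "disease"}
    missing = required - set(df.columns)
    if missing:
        raise CareParseError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise CareValidationError(f"duplicate sample ids in clinical table: {dups[:10]}")
    empty = df.loc[
        df["disease"].isna() | (df["disease"].str.strip() == ""), "sample_id"
    ].tolist()
    if empty:
        raise CareValidationError(
            f"empty disease label for samples: {empty[:10]}"
        )
    return df.set_index("sample_id")


def write_clinical(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name TAB description TAB gene...

    Gene symbols are upper-cased; duplicate set names and short lines are
    errors (the parse error names the offending line).
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CareParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene"
                )
            name, desc, *genes = fields
            if name in sets:
                raise CareValidationError(
                    f"{path}: duplicate gene-set name {name!r} at line {lineno}"
                )
            genes = [g.strip().upper() for g in genes if g.strip()]
            if not genes:
                raise CareParseError(f"{path}: line {lineno} lists no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, source_label=str(path),
                             descriptions=descriptions).validate()


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_drug_table(
    path, allowed_sources=DGIDB_CANCER_SOURCES
) -> DrugInteractionTable:
    """Read a drug–gene interaction TSV restricted to ``allowed_sources``.

    Columns ``gene, drug, source, interaction_type`` are required.  Rows
    from other sources are dropped with a logged count; fully duplicated
    rows (after upper-casing the gene symbol) are collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "drug", "source", "interaction_type"}
    missing = required - set(df.columns)
    if missing:
        raise CareParseError(f"drug table missing columns: {sorted(missing)}")
    allowed = tuple(allowed_sources)
    if not allowed:
        warnings.warn("empty allowed_sources: drug table will be empty", stacklevel=2)
    df = df[list(sorted(required))].copy()
    df["gene"] = df["gene"].str.strip().str.upper()
    kept = df[df["source"].isin(allowed)].drop_duplicates().reset_index(drop=True)
    n_dropped = len(df) - len(df[df["source"].isin(allowed)])
    if n_dropped:
        logger.info("dropped %d drug-interaction rows from other sources", n_dropped)
    cols = ["gene", "drug", "source", "interaction_type"]
    return DrugInteractionTable(rows=kept[cols], allowed_sources=allowed)


def write_drug_table(table: DrugInteractionTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
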