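"""MEND-read quality gate.

MEND reads are those Mapped to the genome, Exonic, and Non-Duplicate; their
count reflects the integrity and quantity of RNA in a library and indicates
whether the data support robust expression quantification.  This module
operates on abstract per-read boolean flags (or a TSV of them), not on
alignments: the QC concept is fully exercised by the boolean
classification, and a BAM adapter is a documented extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .io import CareValidationError

__all__ = ["QcVerdict", "count_mend", "qc_gate", "read_flags_tsv",
           "DEFAULT_MIN_MEND"]

#: Default pass threshold: 10 million MEND reads (the QC framework's
#: convention; configurable).
DEFAULT_MIN_MEND = 10_000_000


@dataclass
class QcVerdict:
    total_reads: int
    mend_reads: int
    mend_fraction: float
    passed: bool
    threshold: int

    def to_dict(self) -> dict:
        return asdict(self)


def read_flags_tsv(path) -> pd.DataFrame:
    """Read a per-read flags TSV: read_id, mapped, exonic, duplicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "mapped", "exonic", "duplicate"}
    missing = required - set(df.columns)
    if missing:
        raise CareValidationError(f"flags TSV missing columns: {sorted(missing)}")
    for col in ("mapped", "exonic", "duplicate"):
        df[col] = df[col].astype(bool)
    return df


def count_mend(records: pd.DataFrame) -> tuple[int, int]:
    """Count total and MEND (mapped AND exonic AND not duplicate) reads.

    An exonic-but-unmapped record is inconsistent and raises.
    """
    bad = records["exonic"] & ~records["mapped"]
    if bad.any():
        ids = records.loc[bad, "read_id"].head(5).tolist()
        raise CareValidationError(f"exonic but unmapped reads: {ids}")
    mend = int(
        (records["mapped"] & records["exonic"] & ~records["duplicate"]).sum()
    )
    return len(records), mend


def qc_gate(total: int, mend: int, min_mend: int = DEFAULT_MIN_MEND) -> QcVerdict:
    """Pass iff the MEND count reaches ``min_mend`` (boundary inclusive)."""
    if not 0 <= mend <= total:
        raise CareValidationError("inconsistent counts: need 0 <= mend <= total")
    return QcVerdict(
        total_reads=total,
        mend_reads=mend,
        mend_fraction=(mend / total) if total else 0.0,
        passed=mend >= min_mend,
        threshold=min_mend,
    )
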