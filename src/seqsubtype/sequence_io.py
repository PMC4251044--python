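"""Reading, validating and summarizing protein sequence sets.

Sequences are restricted to the 20 standard one-letter residue codes;
records carrying ambiguous or non-standard characters (B, J, O, U, X, Z,
``*``, gap symbols) are either dropped with a log message or rejected,
depending on policy.  Length summaries follow the usual box-plot
convention: quartiles by linear interpolation, outliers beyond 1.5 IQR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from seqsubtype.errors import FastaFormatError, InvalidResidueError, SeqSubtypeError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed order used by all descriptors.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    Attributes
    ----------
    id : str
        Unique identifier within a dataset.
    description : str
        Free-text description (may be empty).
    sequence : str
        Uppercase string over the 20 standard residue codes; non-empty.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqSubtypeError("record id must be non-empty")
        if not self.sequence:
            raise InvalidResidueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise InvalidResidueError(
                f"record {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthSummary:
    """Five-number length summary plus 1.5-IQR outlier ids."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outlier_ids: tuple[str, ...] = field(default_factory=tuple)


def read_fasta(path: str | Path, policy: Literal["drop", "error"] = "drop") -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Lowercase residues are uppercased before validation.  With
    ``policy="drop"``, records containing non-standard characters are
    excluded and logged; with ``policy="error"`` the first such record
    aborts the read.

    Raises
    ------
    FastaFormatError
        For structurally broken input (record with an empty sequence, or a
        file with sequence data before any header).
    InvalidResidueError
        Under ``policy="error"`` when a record has non-standard residues.
    """
    if policy not in ("drop", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith((">", ";")) and first.strip():
            raise FastaFormatError(f"{path}: line 1: expected FASTA header, got {first.strip()[:40]!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        try:
            record = ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        except InvalidResidueError:
            if policy == "error":
                raise
            logger.info("dropping record %r: non-standard residues", rec.id)
            continue
        seen.add(record.id)
        records.append(record)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def length_summary(records: list[ProteinRecord]) -> LengthSummary:
    """Quartile summary of sequence lengths with 1.5-IQR outlier detection."""
    if not records:
        raise ValueError("length_summary requires at least one record")
    lengths = np.array([len(r) for r in records], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(r.id for r, L in zip(records, lengths) if L < lo or L > hi)
    return LengthSummary(
        n=len(records),
        min=float(lengths.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(lengths.max()),
        outlier_ids=outliers,
    )


def write_length_table(records: list[ProteinRecord], path: str | Path) -> None:
    """Write a two-column (id, length) TSV."""
    df = pd.DataFrame({"id": [r.id for r in records], "length": [len(r) for r in records]})
    df.to_csv(path, sep="\t", index=False)
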