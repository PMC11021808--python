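"""FASTA input/output, residue encoding, database batching, tabular reporting.

Reading goes through Biopython's SeqIO; records are immediately ordinal-encoded
(:mod:`seedvote.alphabet`). Coordinates are 0-based half-open everywhere inside
the package and converted to 1-based inclusive only when a BLAST-tabular line
is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Union

import numpy as np
from Bio import SeqIO

from .alphabet import AlphabetError, decode, encode


class FastaError(ValueError):
    """Malformed FASTA input (bad structure, duplicate ids, bad residues)."""


@dataclass
class SequenceRecord:
    """One encoded protein sequence.

    Attributes
    ----------
    id : str
        First whitespace-delimited word of the FASTA header; unique per file.
    description : str
        Remainder of the header (may be empty).
    residues : np.ndarray
        Ordinal-encoded residues (uint8); ambiguity codes share one ordinal.
    mask : np.ndarray
        Per-position bool; True = excluded from k-mer seeding (soft mask).
    """

    id: str
    description: str
    residues: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.residues), dtype=bool)
        if len(self.mask) != len(self.residues):
            raise ValueError("mask and residues must have equal length")
        if not self.id:
            raise ValueError("record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        """Residues as a string (excluded ordinals render as 'X')."""
        return decode(self.residues)


@dataclass
class DatabaseBatch:
    """A memory-budgeted slice of the database, scanned in one pass.

    ``subject_offset`` is the global 0-based index of the first record, so
    subject numbering is identical whatever the batch budget.
    """

    batch_index: int
    records: List[SequenceRecord]
    total_residues: int
    subject_offset: int = 0


def record_from_string(rec_id: str, sequence: str, description: str = "") -> SequenceRecord:
    return SequenceRecord(id=rec_id, description=description, residues=encode(sequence))


def read_fasta(path: Union[str, Path, IO[str]]) -> List[SequenceRecord]:
    """Read a protein FASTA file into encoded records, order preserved.

    Raises :class:`FastaError` on a sequence line before any header, a
    duplicate id, or a character outside the protein alphabet.
    """
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            return read_fasta(handle)

    # SeqIO silently tolerates leading junk; reject it explicitly.
    first = None
    for line in path:
        if line.strip():
            first = line
            break
    if first is None:
        return []
    if not first.startswith(">"):
        raise FastaError(
            f"sequence line before any FASTA header: {first.strip()[:40]!r}"
        )
    path.seek(0)

    records: List[SequenceRecord] = []
    seen = set()
    for entry in SeqIO.parse(path, "fasta"):
        if entry.id in seen:
            raise FastaError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        try:
            residues = encode(str(entry.seq).upper())
        except AlphabetError as exc:
            raise FastaError(f"record {entry.id!r}: {exc}") from exc
        records.append(SequenceRecord(id=entry.id, description=desc, residues=residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path, IO[str]],
                width: int = 60) -> None:
    """Write records as FASTA (used for fixtures and round-trip tests)."""
    if isinstance(path, (str, Path)):
        with open(path, "w") as handle:
            write_fasta(records, handle, width)
        return
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        path.write(header + "\n")
        seq = rec.sequence()
        for i in range(0, len(seq), width):
            path.write(seq[i:i + width] + "\n")


def split_database(records: Sequence[SequenceRecord], budget: int) -> List[DatabaseBatch]:
    """Greedy first-fit split of the database into residue-budgeted batches.

    A record never spans two batches; a single record longer than the budget
    gets a batch of its own. Concatenating batches in order reproduces the
    input order exactly.
    """
    if budget < 1:
        raise ValueError(f"batch budget must be >= 1, got {budget}")
    batches: List[DatabaseBatch] = []
    current: List[SequenceRecord] = []
    current_residues = 0
    offset = 0
    for rec in records:
        if current and current_residues + rec.length > budget:
            batches.append(DatabaseBatch(len(batches), current, current_residues,
                                         subject_offset=offset))
            offset += len(current)
            current, current_residues = [], 0
        current.append(rec)
        current_residues += rec.length
    if current:
        batches.append(DatabaseBatch(len(batches), current, current_residues,
                                     subject_offset=offset))
    return batches


def format_evalue(evalue: float) -> str:
    """Render an E-value the BLAST-tabular way.

    Shortest of fixed-point and scientific notation; scientific uses a
    lowercase 'e' and a two-digit signed exponent; ties go to fixed-point.
    """
    if evalue <= 0:
        return "0"
    sci = f"{evalue:.1e}"
    mant, expo = sci.split("e")
    mant = mant.rstrip("0").rstrip(".")
    sci = f"{mant}e{expo}"
    # fixed-point with two significant digits
    exp10 = math.floor(math.log10(evalue))
    ndec = max(0, 1 - exp10)
    if ndec > 12:  # fixed form hopeless; scientific wins anyway
        return sci
    fixed = f"{evalue:.{ndec}f}"
    if "." in fixed:
        fixed = fixed.rstrip("0").rstrip(".")
    if not fixed or float(fixed) == 0.0:
        return sci
    return fixed if len(fixed) <= len(sci) else sci


def tabular_line(hit) -> str:
    """One BLAST outfmt-6 line (12 tab-separated fields) for an AlignmentResult."""
    fields = [
        hit.query_id,
        hit.subject_id,
        f"{hit.identity_pct:.2f}",
        str(hit.align_length),
        str(hit.mismatches),
        str(hit.gap_opens),
        str(hit.q_start + 1),
        str(hit.q_end),
        str(hit.s_start + 1),
        str(hit.s_end),
        format_evalue(hit.evalue),
        f"{hit.bit_score:.1f}",
    ]
    return "\t".join(fields)


def write_tabular_hits(hits, sink: Union[str, Path, IO[str]]) -> None:
    """Write ranked hits in BLAST outfmt-6; coordinates 1-based inclusive."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as handle:
            write_tabular_hits(hits, handle)
        return
    for hit in hits:
        sink.write(tabular_line(hit) + "\n")
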