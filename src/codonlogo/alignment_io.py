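"""Reading, validating, filtering and writing nucleotide alignments.

An alignment here is an ordered list of equal-length records over the
IUPAC nucleotide alphabet (plus the ``-`` gap character), with a total
length that is a multiple of three so the sequences can be tokenized
into codons downstream.

Normalization performed at parse time:

* sequences are uppercased;
* ``U`` is mapped to ``T`` so RNA and DNA inputs are treated uniformly.

Gaps are accepted but are never counted as ambiguous nucleotides, and
the ambiguity-fraction denominator excludes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import (
    AlignmentError,
    AlphabetError,
    EmptyAfterFilterError,
    EmptyInputError,
    FrameError,
    UndefinedFractionError,
)

logger = logging.getLogger(__name__)

#: Unambiguous nucleotide codes.
STANDARD_NUCLEOTIDES = frozenset("ACGT")

#: IUPAC ambiguity codes (everything that is a nucleotide symbol but not ACGT).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

#: Gap character accepted in aligned input.
GAP = "-"

#: Full allowed alphabet after normalization.
ALLOWED_CHARACTERS = STANDARD_NUCLEOTIDES | AMBIGUITY_CODES | {GAP}

#: Recommended minimum number of sequences to avoid entropy underestimation.
MIN_RECOMMENDED_SEQUENCES = 40


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its FASTA identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_CHARACTERS
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: disallowed character(s) "
                f"{', '.join(sorted(bad))}"
            )


@dataclass
class Alignment:
    """Ordered collection of equal-length :class:`SequenceRecord` objects."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(
                f"alignment length {length} is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns (nucleotides)."""
        return len(self.records[0].sequence)

    @property
    def n_codons(self) -> int:
        """Number of codon positions."""
        return self.length // 3

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records


@dataclass(frozen=True)
class FilterReport:
    """What a filtering step removed and why."""

    rule: str  # "uncertainty" | "duplicate"
    n_input: int
    removed_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_removed > self.n_input:
            raise ValueError("removed more records than were supplied")

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA ``U`` to ``T``."""
    return raw.upper().replace("U", "T")


def read_fasta_alignment(path: Union[str, Path]) -> Alignment:
    """Parse a FASTA file into a validated, normalized :class:`Alignment`.

    Raises
    ------
    EmptyInputError
        If the file contains no records.
    AlignmentError, FrameError, AlphabetError
        If the records violate alignment, frame or alphabet constraints.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq)))
        )
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    aln = Alignment(records)
    if len(aln) < MIN_RECOMMENDED_SEQUENCES:
        logger.warning(
            "alignment has only %d sequences; entropy may be underestimated "
            "with fewer than %d",
            len(aln),
            MIN_RECOMMENDED_SEQUENCES,
        )
    return aln


def ambiguity_fraction(record: SequenceRecord) -> float:
    """Percentage of ambiguous nucleotides among the non-gap characters.

    Returns a value in ``[0, 100]``. Gaps are excluded from both the
    numerator and the denominator.
    """
    non_gap = [c for c in record.sequence if c != GAP]
    if not non_gap:
        raise UndefinedFractionError(
            f"record {record.id!r} is all gaps; ambiguity fraction undefined"
        )
    n_ambiguous = sum(1 for c in non_gap if c in AMBIGUITY_CODES)
    return 100.0 * n_ambiguous / len(non_gap)


def filter_by_uncertainty(
    aln: Alignment, threshold: float
) -> tuple[Alignment, FilterReport]:
    """Drop records whose ambiguity fraction strictly exceeds ``threshold``.

    The comparison is strictly-greater-than: a 12-nt sequence with 3
    ambiguous characters (25%) survives a 30% threshold, while one with
    4 (33.3%) does not.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    survivors, removed = [], []
    for rec in aln:
        if ambiguity_fraction(rec) > threshold:
            removed.append(rec.id)
        else:
            survivors.append(rec)
    report = FilterReport(
        rule="uncertainty", n_input=len(aln), removed_ids=tuple(removed)
    )
    if not survivors:
        raise EmptyAfterFilterError(
            f"uncertainty filter at {threshold}% removed all "
            f"{len(aln)} sequences"
        )
    return Alignment(survivors), report


def deduplicate(aln: Alignment) -> tuple[Alignment, FilterReport]:
    """Keep only the first record of each identical-sequence group.

    Identity is exact string equality of the normalized sequences;
    headers are ignored. Idempotent.
    """
    seen: set[str] = set()
    survivors, removed = [], []
    for rec in aln:
        if rec.sequence in seen:
            removed.append(rec.id)
        else:
            seen.add(rec.sequence)
            survivors.append(rec)
    report = FilterReport(
        rule="duplicate", n_input=len(aln), removed_ids=tuple(removed)
    )
    return Alignment(survivors), report


def write_fasta(aln: Alignment, path: Union[str, Path], width: int = 60) -> Path:
    """Write the alignment as multi-record FASTA, wrapped at ``width`` chars."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in aln
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)
    return path
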