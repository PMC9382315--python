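"""Position x codon count / probability / information matrices.

The pipeline is::

    Alignment -> count_codons -> to_probability -> to_bits

At each codon position ``l`` with symbol frequencies ``f(n, l)``:

* observed entropy           ``H(l)   = -sum_n f(n,l) * log2 f(n,l)``
* information content        ``Rseq(l) = Smax - H(l)``
* per-symbol glyph height    ``Height(n,l) = f(n,l) * Rseq(l)``

``Smax = log2(N)`` is the maximum entropy of the symbol alphabet:
6 bits for the 64 unambiguous codons. When ambiguity codes survive
filtering and are counted as symbols in their own right, the alphabet
grows to the 15^3 = 3375 IUPAC triplets and Smax inflates accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment_io import AMBIGUITY_CODES, GAP, Alignment
from .errors import (
    AlphabetMismatchError,
    ContractError,
    DegenerateColumnError,
    FrameError,
)

#: Size of the unambiguous codon alphabet.
N_UNAMBIGUOUS_CODONS = 64

#: Size of the extended alphabet of all IUPAC nucleotide triplets (15^3).
N_AMBIGUOUS_CODONS = 15 ** 3

#: Marker for a codon excluded from counting (contains a gap).
GAP_CODON = None


@dataclass(frozen=True)
class AlphabetSpec:
    """Symbol alphabet determining Smax.

    ``mode`` is one of ``"unambiguous64"``, ``"ambiguous_extended"`` or
    ``"explicit"`` (arbitrary user-supplied symbol count).
    """

    n_symbols: int
    mode: str = "explicit"

    def __post_init__(self) -> None:
        if self.n_symbols < 2:
            raise ValueError(f"n_symbols must be >= 2, got {self.n_symbols}")
        expected = {
            "unambiguous64": N_UNAMBIGUOUS_CODONS,
            "ambiguous_extended": N_AMBIGUOUS_CODONS,
        }
        if self.mode in expected and self.n_symbols != expected[self.mode]:
            raise ValueError(
                f"mode {self.mode!r} requires n_symbols == "
                f"{expected[self.mode]}, got {self.n_symbols}"
            )

    @classmethod
    def unambiguous(cls) -> "AlphabetSpec":
        return cls(N_UNAMBIGUOUS_CODONS, "unambiguous64")

    @classmethod
    def ambiguous_extended(cls) -> "AlphabetSpec":
        return cls(N_AMBIGUOUS_CODONS, "ambiguous_extended")


def compute_smax(spec: AlphabetSpec) -> float:
    """Maximum possible entropy, ``log2(n_symbols)``, in bits."""
    return math.log2(spec.n_symbols)


def tokenize_codons(sequence: str) -> list[Optional[str]]:
    """Split a sequence into non-overlapping frame-0 triplets.

    Triplets containing a gap character are returned as ``None`` and are
    excluded from counting downstream.
    """
    if len(sequence) % 3 != 0:
        raise FrameError(
            f"sequence length {len(sequence)} is not a multiple of 3"
        )
    codons: list[Optional[str]] = []
    for i in range(0, len(sequence), 3):
        codon = sequence[i : i + 3]
        codons.append(GAP_CODON if GAP in codon else codon)
    return codons


@dataclass
class CodonCountMatrix:
    """Integer codon counts per 1-based codon position.

    ``counts`` has one row per position and one (lexicographically
    sorted) column per codon observed anywhere in the alignment.
    """

    positions: list[int]
    codons: list[str]
    counts: np.ndarray  # (n_positions, n_codons) ints
    n_sequences: int

    @property
    def depth_per_position(self) -> np.ndarray:
        """Counted (non-gap) codons at each position."""
        return self.counts.sum(axis=1)

    def has_ambiguous_codons(self) -> bool:
        """True if any counted codon column contains an ambiguity code."""
        return any(
            any(c in AMBIGUITY_CODES for c in codon) for codon in self.codons
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.codons)
        df.insert(0, "position", self.positions)
        return df.set_index("position")


@dataclass
class ProbabilityMatrix:
    """Per-position codon proportions; each row sums to 1."""

    positions: list[int]
    codons: list[str]
    values: np.ndarray  # (n_positions, n_codons) floats

    def row(self, position: int) -> dict[str, float]:
        i = self.positions.index(position)
        return dict(zip(self.codons, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.codons)
        df.insert(0, "position", self.positions)
        return df.set_index("position")


@dataclass
class BitMatrix:
    """Per-position glyph heights in bits, with entropy metadata."""

    positions: list[int]
    codons: list[str]
    values: np.ndarray  # Height(n, l)
    entropy: np.ndarray  # H(l)
    rseq: np.ndarray  # Rseq(l) = smax - H(l)
    smax: float

    def row(self, position: int) -> dict[str, float]:
        i = self.positions.index(position)
        return dict(zip(self.codons, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.codons)
        df.insert(0, "position", self.positions)
        return df.set_index("position")


def count_codons(aln: Alignment) -> CodonCountMatrix:
    """Tally codons per position over all sequences.

    Gap-containing triplets are skipped, so the per-position depth can
    be below the number of sequences.
    """
    tokenized = [tokenize_codons(rec.sequence) for rec in aln]
    observed = sorted(
        {c for row in tokenized for c in row if c is not GAP_CODON}
    )
    col_index = {c: j for j, c in enumerate(observed)}
    n_positions = aln.n_codons
    counts = np.zeros((n_positions, len(observed)), dtype=np.int64)
    for row in tokenized:
        for pos, codon in enumerate(row):
            if codon is not GAP_CODON:
                counts[pos, col_index[codon]] += 1
    return CodonCountMatrix(
        positions=list(range(1, n_positions + 1)),
        codons=observed,
        counts=counts,
        n_sequences=len(aln),
    )


def to_probability(
    counts: CodonCountMatrix, drop_empty_positions: bool = False
) -> ProbabilityMatrix:
    """Normalize counts to per-position proportions.

    A position where every sequence had a gap-codon has depth 0 and no
    defined distribution; by default this is an error, or the position
    is silently dropped when ``drop_empty_positions`` is set.
    """
    depth = counts.depth_per_position
    if drop_empty_positions:
        keep = depth > 0
        positions = [p for p, k in zip(counts.positions, keep) if k]
        mat = counts.counts[keep]
        depth = depth[keep]
    else:
        empty = [p for p, d in zip(counts.positions, depth) if d == 0]
        if empty:
            raise DegenerateColumnError(
                f"no counted codons at position(s) {empty}; "
                "every sequence has a gap there"
            )
        positions = list(counts.positions)
        mat = counts.counts
    values = mat.astype(float) / depth[:, None]
    return ProbabilityMatrix(
        positions=positions, codons=list(counts.codons), values=values
    )


def position_entropy(prob_row: Sequence[float], tol: float = 1e-6) -> float:
    """Shannon entropy ``-sum f*log2(f)`` of one probability row, in bits.

    Zero entries contribute nothing (0 * log2(0) := 0).
    """
    row = np.asarray(prob_row, dtype=float)
    if row.min() < -tol or row.max() > 1 + tol:
        raise ContractError("probabilities must lie in [0, 1]")
    total = row.sum()
    if abs(total - 1.0) > tol:
        raise ContractError(f"probability row sums to {total}, expected 1")
    nz = row[row > 0]
    return float(-(nz * np.log2(nz)).sum())


def select_alphabet(counts: CodonCountMatrix) -> AlphabetSpec:
    """Default Smax alphabet: 64 codons, or the 3375 IUPAC triplets if
    ambiguity codes survived filtering into the counted data."""
    if counts.has_ambiguous_codons():
        return AlphabetSpec.ambiguous_extended()
    return AlphabetSpec.unambiguous()


def to_bits(prob: ProbabilityMatrix, smax: float) -> BitMatrix:
    """Transform proportions into glyph heights in bits.

    ``Height(n,l) = f(n,l) * (smax - H(l))``; raises
    :class:`AlphabetMismatchError` if any observed entropy exceeds
    ``smax`` (the alphabet was chosen too small).
    """
    entropy = np.array([position_entropy(row) for row in prob.values])
    if (entropy > smax + 1e-9).any():
        worst = prob.positions[int(entropy.argmax())]
        raise AlphabetMismatchError(
            f"entropy {entropy.max():.6f} bits at position {worst} exceeds "
            f"Smax={smax:.6f}; choose a larger alphabet"
        )
    rseq = np.clip(smax - entropy, 0.0, None)
    values = prob.values * rseq[:, None]
    return BitMatrix(
        positions=list(prob.positions),
        codons=list(prob.codons),
        values=values,
        entropy=entropy,
        rseq=rseq,
        smax=smax,
    )


def write_matrix(
    matrix: Union[ProbabilityMatrix, BitMatrix], path: Union[str, Path]
) -> Path:
    """Write a matrix as CSV: ``position`` column plus one column per codon.

    Values are written at full double precision (shortest round-tripping
    decimal repr), so a re-read reproduces the matrix exactly.
    """
    path = Path(path)
    df = matrix.to_frame()
    df.to_csv(path, index=True)
    return path


def read_matrix_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a matrix CSV written by :func:`write_matrix`."""
    return pd.read_csv(path, index_col="position")
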