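"""Sequence and scoring-scheme I/O.

Reads FASTA/FASTQ records and NCBI-format substitution matrices, builds DNA
match/mismatch schemes, and encodes residue strings into the integer alphabet
used by the alignment engine.

Conventions:

* residues are uppercased on input; soft-masking (lowercase) is ignored;
* gap penalties are stored as non-negative magnitudes and subtracted by the
  dynamic programs (a gap of length k costs ``gap_open + (k-1)*gap_extend``);
* every alphabet carries one wildcard symbol (``N`` for DNA, ``X`` for
  protein); residues not in the alphabet encode to the wildcard index.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "FormatError",
    "SequenceRecord",
    "ScoringScheme",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "parse_score_matrix",
    "make_dna_scheme",
    "encode",
    "BUILTIN_MATRICES",
]

#: builtin substitution matrices resolvable by name (via Biopython's
#: canonical copies of the NCBI files).
BUILTIN_MATRICES = ("BLOSUM45", "BLOSUM50", "BLOSUM62", "BLOSUM80", "BLOSUM90",
                    "PAM30", "PAM70", "PAM250")


class FormatError(ValueError):
    """Malformed input file (FASTA/FASTQ/matrix)."""


@dataclass
class SequenceRecord:
    """A named residue string, with per-base qualities when read from FASTQ."""

    id: str
    residues: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(eq=False)
class ScoringScheme:
    """Alphabet, substitution table and affine-gap penalty magnitudes.

    ``scores`` is a square integer table indexed by alphabet position; the
    wildcard symbol is part of the alphabet.  ``gap_open`` is the cost of the
    first gapped residue, ``gap_extend`` of each further one.
    """

    alphabet: str
    scores: np.ndarray
    gap_open: int = 0
    gap_extend: int = 0
    wildcard: str = "N"
    _lookup: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        a = len(self.alphabet)
        if self.scores.shape != (a, a):
            raise FormatError(
                f"score table shape {self.scores.shape} does not match "
                f"alphabet of size {a}"
            )
        if len(set(self.alphabet)) != a:
            raise ValueError("alphabet has repeated symbols")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative magnitudes")
        if self.wildcard not in self.alphabet:
            raise ValueError(f"wildcard {self.wildcard!r} not in alphabet")
        if not (self.scores > 0).any():
            raise ValueError("score table has no positive entry; every local "
                             "alignment would be empty")
        # byte -> alphabet index, case-insensitive, unknowns -> wildcard
        table = np.full(256, self.alphabet.index(self.wildcard), dtype=np.intp)
        for i, sym in enumerate(self.alphabet):
            table[ord(sym.upper())] = i
            table[ord(sym.lower())] = i
        self._lookup = table

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def index(self, symbol: str) -> int:
        return int(self._lookup[ord(symbol)])

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.index(a), self.index(b)])

    def with_gaps(self, gap_open: int, gap_extend: int) -> "ScoringScheme":
        return replace(self, gap_open=gap_open, gap_extend=gap_extend)

    def scaled(self, c: int) -> "ScoringScheme":
        """Multiply every score and penalty by a positive integer."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return ScoringScheme(self.alphabet, self.scores * c,
                             self.gap_open * c, self.gap_extend * c,
                             self.wildcard)


def _records_from(handle_or_path, fmt: str) -> list[SequenceRecord]:
    out: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(handle_or_path, fmt):
            quals = None
            if fmt == "fastq":
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append(SequenceRecord(rec.id, str(rec.seq).upper(), quals))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FormatError(str(exc)) from exc
    if not out:
        raise FormatError(f"no {fmt.upper()} records found")
    return out


def read_fasta(path) -> list[SequenceRecord]:
    """Read all records of a FASTA file (wrapped lines are concatenated)."""
    return _records_from(path, "fasta")


def read_fastq(path) -> list[SequenceRecord]:
    """Read all records of a 4-line-per-record Sanger FASTQ file."""
    return _records_from(path, "fastq")


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    close = False
    if isinstance(path, (str, os.PathLike)):
        handle = open(path, "w")
        close = True
    else:
        handle = path
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


def parse_score_matrix(source) -> ScoringScheme:
    """Load a substitution matrix by builtin name or from an NCBI-format file.

    Returns a :class:`ScoringScheme` with zero gap penalties; combine with
    :meth:`ScoringScheme.with_gaps`.  Builtin names (``BLOSUM50`` ...) resolve
    to the canonical published tables.  The wildcard is ``X`` when present,
    else ``N``, else the last alphabet symbol.
    """
    if isinstance(source, str) and source.upper() in BUILTIN_MATRICES:
        mat = substitution_matrices.load(source.upper())
    else:
        try:
            if hasattr(source, "read"):
                mat = substitution_matrices.read(source)
            else:
                with open(source) as handle:
                    mat = substitution_matrices.read(handle)
        except FileNotFoundError:
            raise KeyError(
                f"{source!r} is neither a builtin matrix name "
                f"({', '.join(BUILTIN_MATRICES)}) nor a readable file"
            ) from None
        except (ValueError, AssertionError, IndexError) as exc:
            raise FormatError(f"malformed substitution matrix: {exc}") from exc
    alphabet = str(mat.alphabet)
    scores = np.asarray(mat)
    if not np.allclose(scores, np.round(scores)):
        raise FormatError("substitution matrix entries must be integers")
    if "X" in alphabet:
        wildcard = "X"
    elif "N" in alphabet:
        wildcard = "N"
    else:
        wildcard = alphabet[-1]
    return ScoringScheme(alphabet, scores.astype(np.int64), 0, 0, wildcard)


def make_dna_scheme(match: int, mismatch: int, gap_open: int,
                    gap_extend: int) -> ScoringScheme:
    """Build the ACGTN scheme: +match on the ACGT diagonal, -mismatch off it.

    ``mismatch`` is a penalty magnitude.  The ambiguity base N scores 0
    against everything (neutral wildcard).
    """
    if match <= 0:
        raise ValueError("match score must be positive")
    if mismatch < 0:
        raise ValueError("mismatch penalty is a non-negative magnitude")
    scores = np.full((5, 5), -int(mismatch), dtype=np.int64)
    np.fill_diagonal(scores, int(match))
    scores[4, :] = 0
    scores[:, 4] = 0
    return ScoringScheme("ACGTN", scores, gap_open, gap_extend, wildcard="N")


def encode(seq: str | SequenceRecord, scheme: ScoringScheme) -> np.ndarray:
    """Map residues to alphabet indices (case-insensitive, total).

    Unknown symbols map to the wildcard index; the output always has the
    input's length.  Empty input is rejected.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError:
        # exotic symbols are still wildcards; keep encode total
        wild = scheme.alphabet.index(scheme.wildcard)
        table = scheme._lookup
        return np.array([table[o] if (o := ord(c)) < 256 else wild
                         for c in seq], dtype=np.intp)
    return scheme._lookup[raw]
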