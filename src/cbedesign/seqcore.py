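"""Nucleotide and codon primitives shared by all other modules.

Sequences are plain uppercase strings over ``{A, C, G, T, N}``; coordinates
are 1-based and inclusive throughout the package, matching the codon
numbering style used in mutation notation (S33L, Q170*, W577*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger("cbedesign")

__all__ = [
    "SequenceError",
    "FrameError",
    "GENETIC_CODE",
    "STOP_CODONS",
    "IUPAC_SETS",
    "normalize",
    "revcomp",
    "iupac_revcomp",
    "translate",
    "codon_at",
    "iupac_match",
    "OpenReadingFrame",
]


class SequenceError(ValueError):
    """Raised for invalid nucleotide input (bad alphabet, empty, wrong length)."""


class FrameError(ValueError):
    """Raised when an operation needs a reading frame that is absent or broken."""


_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code

#: codon -> one-letter amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _TABLE.stop_codons})

STOP_CODONS = frozenset(_TABLE.stop_codons)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide ambiguity codes and the unambiguous bases each matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def normalize(raw: str) -> str:
    """Normalize raw sequence text to an uppercase A/C/G/T/N string.

    Whitespace and line breaks are stripped; lowercase and mixed case are
    accepted. Any other character raises :class:`SequenceError` naming the
    offending character and its 1-based position in the stripped sequence.
    """
    if raw is None or not raw.strip():
        raise SequenceError("empty sequence input")
    seq = "".join(raw.split()).upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in VALID_BASES:
            raise SequenceError(f"invalid character {ch!r} at position {pos}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a normalized sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H...)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def translate(seq: str, truncate: bool = False) -> str:
    """Translate an in-frame sequence with the standard genetic code.

    Stop codons translate to ``'*'``. A codon containing N translates to
    ``'X'`` (flagged ambiguous rather than failing the whole run). When
    *truncate* is true, translation stops at (and includes) the first stop;
    by default the full protein is returned with embedded ``'*'``.
    """
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} is not a multiple of 3")
    out: list[str] = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = GENETIC_CODE.get(codon, "X")
        out.append(aa)
        if truncate and aa == "*":
            break
    return "".join(out)


def codon_at(nt_position: int, length: int | None = None) -> tuple[int, int]:
    """Map a 1-based nucleotide position to (codon_index, offset_within_codon).

    Codon index i covers nucleotides [3i-2, 3i]; the offset is in {1, 2, 3}.
    """
    if nt_position < 1 or (length is not None and nt_position > length):
        raise SequenceError(f"position {nt_position} outside sequence [1, {length}]")
    return (nt_position + 2) // 3, (nt_position - 1) % 3 + 1


def iupac_match(pattern: str, window: str) -> bool:
    """True iff *window* matches the IUPAC *pattern* position by position.

    A sequence N matches only pattern code N (an unknown base cannot be
    trusted to satisfy any narrower code).
    """
    if len(pattern) != len(window):
        raise SequenceError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, b in zip(pattern, window):
        sets = IUPAC_SETS.get(p)
        if sets is None:
            raise SequenceError(f"unknown IUPAC code {p!r} in pattern")
        if b == "N":
            if p != "N":
                return False
        elif b not in sets:
            return False
    return True


@dataclass(frozen=True)
class OpenReadingFrame:
    """An in-frame coding sequence.

    Length must be a multiple of 3. A non-ATG start is permitted with a
    logged warning (partial ORFs and downstream exons are legitimate
    inputs); internal stop codons are likewise permitted — the guide
    search simply never targets a codon that is already a stop.
    """

    sequence: str

    def __post_init__(self) -> None:
        seq = normalize(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) % 3 != 0:
            raise FrameError(
                f"ORF length {len(seq)} is not a multiple of 3; supply an in-frame sequence"
            )
        if not seq.startswith("ATG"):
            logger.warning("ORF does not start with ATG (starts %s)", seq[:3])

    @classmethod
    def from_raw(cls, raw: str) -> "OpenReadingFrame":
        return cls(normalize(raw))

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def codon_count(self) -> int:
        return len(self.sequence) // 3

    def codon(self, index: int) -> str:
        """The codon at 1-based *index*."""
        if not 1 <= index <= self.codon_count:
            raise SequenceError(f"codon index {index} outside [1, {self.codon_count}]")
        return self.sequence[3 * (index - 1) : 3 * index]

    def codon_at(self, nt_position: int) -> tuple[int, int]:
        return codon_at(nt_position, length=len(self.sequence))

    def protein(self, truncate: bool = False) -> str:
        return translate(self.sequence, truncate=truncate)
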