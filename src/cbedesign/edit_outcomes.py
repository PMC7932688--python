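"""Enumeration and classification of base-editing haplotypes.

Deamination of the window cytosines is stochastic per molecule, so a guide
produces a mixture of haplotypes — every subset of its editable Cs. This
module applies such subsets to the coding sequence and classifies the
protein consequence of each (nonsense / missense / silent / mixed / none).
Haplotype frequencies are not modeled; the enumeration is combinatorial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .guide_design import (
    DEFAULT_WINDOW,
    Bystander,
    EditableCytosine,
    EditingWindow,
    GuideSite,
    editable_cytosines,
)
from .seqcore import GENETIC_CODE, FrameError, OpenReadingFrame, SequenceError

__all__ = [
    "CodonChange",
    "EditOutcome",
    "enumerate_edit_combinations",
    "apply_edits",
    "classify_outcome",
    "classify_edits",
    "single_edit_summary",
    "protein_diff",
]

#: precedence when a haplotype touches several codons
_CLASS_ORDER = ("nonsense", "mixed", "missense", "silent", "none")


@dataclass(frozen=True)
class CodonChange:
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.ref_codon}>{self.alt_codon}({self.ref_aa}{self.codon_index}{self.alt_aa})"


@dataclass(frozen=True)
class EditOutcome:
    """One haplotype: an edited-C subset and its codon/protein consequences."""

    edited: tuple[EditableCytosine, ...]
    codon_changes: tuple[CodonChange, ...]
    outcome_class: str
    truncation_codon: int | None = None

    @property
    def edited_distances(self) -> tuple[int, ...]:
        return tuple(c.d for c in self.edited)


def classify_outcome(codon_changes: tuple[CodonChange, ...] | list[CodonChange]) -> str:
    """Consequence class of a set of codon changes.

    nonsense if any change introduces a stop; otherwise missense if all
    amino acids change, silent if none do, mixed when silent and missense
    coexist. Nonsense dominates every other class.
    """
    if not codon_changes:
        return "none"
    if any(ch.alt_aa == "*" for ch in codon_changes):
        return "nonsense"
    n_missense = sum(1 for ch in codon_changes if ch.ref_aa != ch.alt_aa)
    if n_missense == 0:
        return "silent"
    if n_missense == len(codon_changes):
        return "missense"
    return "mixed"


def classify_edits(
    orf: OpenReadingFrame, edited: tuple[EditableCytosine, ...]
) -> EditOutcome:
    """Apply an edited-C subset jointly and classify the consequence.

    Cs sharing a codon are evaluated on the jointly mutated codon, never
    per edit independently.
    """
    by_codon: dict[int, list[EditableCytosine]] = {}
    for c in edited:
        if c.codon_index is None:
            raise FrameError(
                f"edited base at coordinate {c.input_coordinate} has no codon "
                "assignment; supply the full ORF or the guide's frame"
            )
        by_codon.setdefault(c.codon_index, []).append(c)
    changes: list[CodonChange] = []
    for codon_index in sorted(by_codon):
        ref = orf.codon(codon_index)
        bases = list(ref)
        for c in by_codon[codon_index]:
            bases[c.codon_offset - 1] = "T" if c.sense_change == "C>T" else "A"
        alt = "".join(bases)
        if alt != ref:
            changes.append(
                CodonChange(codon_index, ref, alt, GENETIC_CODE[ref], GENETIC_CODE[alt])
            )
    truncation = min(
        (ch.codon_index for ch in changes if ch.alt_aa == "*"), default=None
    )
    return EditOutcome(
        edited=tuple(edited),
        codon_changes=tuple(changes),
        outcome_class=classify_outcome(changes),
        truncation_codon=truncation,
    )


def single_edit_summary(orf: OpenReadingFrame, c: EditableCytosine) -> Bystander:
    """Bystander summary for one window C edited alone."""
    if c.codon_index is None:
        return Bystander(d=c.d, outcome_class="unknown", codon_change="",
                         protein_change="")
    outcome = classify_edits(orf, (c,))
    if not outcome.codon_changes:  # edit is a no-op (cannot happen for a C/G base)
        return Bystander(d=c.d, outcome_class="none", codon_change="", protein_change="")
    ch = outcome.codon_changes[0]
    protein = (
        f"{ch.ref_aa}{ch.codon_index}="
        if ch.ref_aa == ch.alt_aa
        else f"{ch.ref_aa}{ch.codon_index}{ch.alt_aa}"
    )
    return Bystander(
        d=c.d,
        outcome_class=outcome.outcome_class,
        codon_change=f"{ch.ref_codon}>{ch.alt_codon}",
        protein_change=protein,
    )


def enumerate_edit_combinations(
    site: GuideSite,
    window: EditingWindow = DEFAULT_WINDOW,
    orf: OpenReadingFrame | None = None,
) -> list[EditOutcome]:
    """All 2^k haplotypes over the k editable Cs of *site*, fully classified.

    Ordered by subset size, then lexicographically by decreasing-distance
    tuples. Requires every window C to map onto the ORF (the frame must be
    known); a site whose window leaves the ORF raises :class:`FrameError`.
    """
    if orf is None:
        raise FrameError("enumerate_edit_combinations requires the ORF to map codons")
    cytosines = editable_cytosines(site, window, orf)
    if any(c.codon_index is None for c in cytosines):
        raise FrameError(
            "editing window extends outside the ORF; supply flanking context "
            "through find_stop_guides or trim the guide"
        )
    outcomes: list[EditOutcome] = []
    for r in range(len(cytosines) + 1):
        for subset in itertools.combinations(cytosines, r):
            outcomes.append(classify_edits(orf, subset))
    outcomes.sort(key=lambda o: (len(o.edited), o.edited_distances))
    return outcomes


def apply_edits(orf: OpenReadingFrame, outcome: EditOutcome) -> OpenReadingFrame:
    """Return the ORF with the outcome's conversions applied.

    Each edit is C->T (sense guide) or G->A (antisense guide) at its
    coding-strand coordinate; length is unchanged and no other position is
    touched.
    """
    bases = list(orf.sequence)
    for c in outcome.edited:
        pos = c.input_coordinate
        if not 1 <= pos <= len(bases):
            raise SequenceError(f"edit coordinate {pos} outside ORF [1, {len(bases)}]")
        expected, new = ("C", "T") if c.sense_change == "C>T" else ("G", "A")
        if bases[pos - 1] != expected:
            raise SequenceError(
                f"edit at {pos} expects {expected} on the coding strand, "
                f"found {bases[pos - 1]}"
            )
        bases[pos - 1] = new
    return OpenReadingFrame("".join(bases))


def protein_diff(before: str, after: str) -> list[str]:
    """Substitutions between two equal-length proteins, as e.g. S33L, W577*."""
    if len(before) != len(after):
        raise SequenceError(
            f"protein lengths differ ({len(before)} vs {len(after)})"
        )
    return [
        f"{b}{i}{a}"
        for i, (b, a) in enumerate(zip(before, after), start=1)
        if b != a
    ]
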