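"""PAM scanning, editable-cytosine enumeration and guide search for CBEs.

A cytidine base editor (CBE) deaminates cytosines on the protospacer strand
within a window a fixed distance upstream of the PAM; the default window is
the closed interval 13-19 nt upstream, with the PAM-proximal protospacer
base at distance 1 (so protospacer 5'->3' index = 21 - d). A guide on the
coding (+) strand therefore performs C->T changes on the coding sequence;
a guide on the antisense (-) strand performs G->A changes. Stop codons are
reachable from exactly {CAA, CAG, CGA} by sense editing and from {TGG} by
antisense editing, which is what the stop-gain search exploits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .seqcore import (
    IUPAC_SETS,
    OpenReadingFrame,
    SequenceError,
    STOP_CODONS,
    GENETIC_CODE,
    iupac_match,
    revcomp,
)

logger = logging.getLogger("cbedesign")

PROTOSPACER_LEN = 20

__all__ = [
    "PROTOSPACER_LEN",
    "PamSpec",
    "EditingWindow",
    "DEFAULT_WINDOW",
    "GuideSite",
    "EditableCytosine",
    "Bystander",
    "GuideReport",
    "SubstitutionUnreachableError",
    "scan_pams",
    "editable_cytosines",
    "position_score",
    "find_stop_guides",
    "find_substitution_guides",
    "rank_guides",
]


class SubstitutionUnreachableError(ValueError):
    """The requested codon change cannot be produced by C->T / G->A chemistry."""


@dataclass(frozen=True)
class PamSpec:
    """A PAM recognition pattern as an IUPAC string, e.g. NGG or NAA."""

    pattern: str
    label: str = ""

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        if len(pattern) < 2:
            raise SequenceError(f"PAM pattern {pattern!r} shorter than 2 nt")
        for ch in pattern:
            if ch not in IUPAC_SETS:
                raise SequenceError(f"unknown IUPAC code {ch!r} in PAM pattern")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class EditingWindow:
    """Closed interval of editable distances upstream of the PAM, in nt."""

    d_min: int = 13
    d_max: int = 19

    def __post_init__(self) -> None:
        if not 1 <= self.d_min <= self.d_max <= PROTOSPACER_LEN:
            raise SequenceError(
                f"window [{self.d_min}, {self.d_max}] must satisfy "
                f"1 <= d_min <= d_max <= {PROTOSPACER_LEN}"
            )

    def __contains__(self, d: int) -> bool:
        return self.d_min <= d <= self.d_max


DEFAULT_WINDOW = EditingWindow()


@dataclass(frozen=True)
class GuideSite:
    """A 20-nt protospacer with its adjacent PAM.

    ``protospacer`` and ``pam`` are given 5'->3' on the guide's own strand;
    ``start``/``end`` are 1-based inclusive coordinates of the protospacer
    on the forward strand of the scanned input (so for strand '-' the
    protospacer equals the reverse complement of input[start..end]).
    ``frame_phase`` is the 0-based offset of ``start`` within its codon when
    the input is an in-frame ORF, else None.
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    end: int
    frame_phase: int | None = None


@dataclass(frozen=True)
class EditableCytosine:
    """One window cytosine of a guide.

    ``d`` is the distance from the PAM (PAM-proximal base has d=1);
    ``protospacer_index`` is the 1-based 5'->3' index (= 21 - d);
    ``input_coordinate`` is the forward-strand coordinate of the edited
    base; ``sense_change`` records the coding-strand chemistry: "C>T" for
    sense guides, "G>A" for antisense guides. Codon fields are None when
    the base falls outside the supplied ORF.
    """

    d: int
    protospacer_index: int
    input_coordinate: int
    sense_change: str
    codon_index: int | None = None
    codon_offset: int | None = None


@dataclass(frozen=True)
class Bystander:
    """Single-edit consequence summary for a window C outside the primary set."""

    d: int
    outcome_class: str
    codon_change: str
    protein_change: str


@dataclass(frozen=True)
class GuideReport:
    """One designed guide: site, window Cs, primary consequence, bystanders."""

    site: GuideSite
    editable: tuple[EditableCytosine, ...]
    target_codon: int
    primary_outcome: "EditOutcome"  # noqa: F821 - defined in edit_outcomes
    bystanders: tuple[Bystander, ...]
    score: float

    @property
    def primary_change(self) -> str:
        """Protein notation of the change at the target codon, e.g. Q170* or D3=."""
        for ch in self.primary_outcome.codon_changes:
            if ch.codon_index == self.target_codon:
                if ch.ref_aa == ch.alt_aa:
                    return f"{ch.ref_aa}{ch.codon_index}="
                return f"{ch.ref_aa}{ch.codon_index}{ch.alt_aa}"
        return ""

    @property
    def nonsilent_bystanders(self) -> int:
        return sum(1 for b in self.bystanders if b.outcome_class not in ("silent", "none"))


def scan_pams(
    seq: str, pam: PamSpec = PamSpec("NGG"), *, framed: bool = False
) -> list[GuideSite]:
    """All 20-nt protospacers immediately 5' of a PAM match, both strands.

    Overlapping sites and duplicate protospacer sequences are all reported.
    Output is ordered by forward-strand start coordinate, '+' before '-'
    at ties. A sequence too short to hold protospacer + PAM yields an
    empty list with a logged notice.
    """
    n, plen = len(seq), pam.length
    sites: list[GuideSite] = []
    if n < PROTOSPACER_LEN + plen:
        logger.info(
            "sequence of %d nt too short for a %d-nt protospacer + %d-nt PAM",
            n, PROTOSPACER_LEN, plen,
        )
        return sites
    # forward strand: protospacer [s, s+19], PAM [s+20, s+20+plen-1]
    for s in range(1, n - PROTOSPACER_LEN - plen + 2):
        pam_seq = seq[s + PROTOSPACER_LEN - 1 : s + PROTOSPACER_LEN + plen - 1]
        if iupac_match(pam.pattern, pam_seq):
            proto = seq[s - 1 : s + PROTOSPACER_LEN - 1]
            sites.append(
                GuideSite(
                    protospacer=proto,
                    pam=pam_seq,
                    strand="+",
                    start=s,
                    end=s + PROTOSPACER_LEN - 1,
                    frame_phase=(s - 1) % 3 if framed else None,
                )
            )
    # reverse strand: protospacer occupies [a, a+19] with PAM at [a-plen, a-1]
    for a in range(plen + 1, n - PROTOSPACER_LEN + 2):
        pam_seq = revcomp(seq[a - plen - 1 : a - 1])
        if iupac_match(pam.pattern, pam_seq):
            proto = revcomp(seq[a - 1 : a + PROTOSPACER_LEN - 1])
            sites.append(
                GuideSite(
                    protospacer=proto,
                    pam=pam_seq,
                    strand="-",
                    start=a,
                    end=a + PROTOSPACER_LEN - 1,
                    frame_phase=(a - 1) % 3 if framed else None,
                )
            )
    sites.sort(key=lambda g: (g.start, 0 if g.strand == "+" else 1))
    _flag_duplicates(sites)
    return sites


def _flag_duplicates(sites: list[GuideSite]) -> None:
    seen: dict[str, int] = {}
    for g in sites:
        seen[g.protospacer] = seen.get(g.protospacer, 0) + 1
    for proto, count in seen.items():
        if count > 1:
            logger.info("protospacer %s is non-unique in input (%d loci)", proto, count)


def editable_cytosines(
    site: GuideSite,
    window: EditingWindow = DEFAULT_WINDOW,
    orf: OpenReadingFrame | None = None,
) -> list[EditableCytosine]:
    """Window cytosines of *site*, sorted by decreasing distance from the PAM.

    With an ORF supplied, each C inside [1, len(orf)] is annotated with its
    codon index and offset; Cs in flanking sequence keep None there.
    """
    out: list[EditableCytosine] = []
    sense_change = "C>T" if site.strand == "+" else "G>A"
    for i, base in enumerate(site.protospacer, start=1):
        d = PROTOSPACER_LEN + 1 - i
        if base != "C" or d not in window:
            continue
        coord = site.start + i - 1 if site.strand == "+" else site.end - i + 1
        codon_index = codon_offset = None
        if orf is not None and 1 <= coord <= len(orf):
            codon_index, codon_offset = orf.codon_at(coord)
        out.append(
            EditableCytosine(
                d=d,
                protospacer_index=i,
                input_coordinate=coord,
                sense_change=sense_change,
                codon_index=codon_index,
                codon_offset=codon_offset,
            )
        )
    out.sort(key=lambda c: -c.d)
    return out


def position_score(d: int) -> float:
    """Position-dependent editing-efficiency heuristic, in [0, 1].

    Editing is most efficient near the middle of the window and falls below
    detection just outside it, so the default triangular score peaks at
    d=16, reaches 0.25 at the window edges (13, 19) and 0 at d<=12 or
    d>=20. Replaceable by any callable of the same signature wherever a
    scoring hook is accepted.
    """
    return max(0.0, 1.0 - abs(d - 16) / 4.0)


def _mean_score(distances: tuple[int, ...], score=position_score) -> float:
    return sum(score(d) for d in distances) / len(distances) if distances else 0.0


def _mutate_codon(codon: str, edits: dict[int, str]) -> str:
    """Apply {offset (1-3): new_base} to a codon."""
    bases = list(codon)
    for off, b in edits.items():
        bases[off - 1] = b
    return "".join(bases)


def _codon_target_subsets(
    orf: OpenReadingFrame,
    codon_index: int,
    cytosines: list[EditableCytosine],
    accept,
) -> list[tuple[EditableCytosine, ...]]:
    """Edit subsets of *cytosines* (all within *codon_index*) whose joint
    application makes the codon satisfy *accept(mutated_codon)*."""
    original = orf.codon(codon_index)
    hits: list[tuple[EditableCytosine, ...]] = []
    for r in range(1, len(cytosines) + 1):
        for subset in itertools.combinations(cytosines, r):
            edits = {
                c.codon_offset: "T" if c.sense_change == "C>T" else "A" for c in subset
            }
            mutated = _mutate_codon(original, edits)
            if mutated != original and accept(mutated):
                hits.append(subset)
    return hits


def _best_subset(subsets: list[tuple[EditableCytosine, ...]]):
    """Minimal subset; ties broken by higher mean position score, then by
    more PAM-distal distances for determinism."""
    return min(
        subsets,
        key=lambda s: (len(s), -_mean_score(tuple(c.d for c in s)),
                       tuple(-c.d for c in s)),
    )


def _build_report(
    orf: OpenReadingFrame,
    site: GuideSite,
    cytosines: list[EditableCytosine],
    target_codon: int,
    primary_subset: tuple[EditableCytosine, ...],
) -> GuideReport:
    from .edit_outcomes import classify_edits, single_edit_summary

    primary_outcome = classify_edits(orf, primary_subset)
    primary_ids = {c.input_coordinate for c in primary_subset}
    bystanders = tuple(
        single_edit_summary(orf, c)
        for c in cytosines
        if c.input_coordinate not in primary_ids
    )
    return GuideReport(
        site=site,
        editable=tuple(cytosines),
        target_codon=target_codon,
        primary_outcome=primary_outcome,
        bystanders=bystanders,
        score=_mean_score(tuple(c.d for c in primary_subset)),
    )


def _scan_orf_sites(
    orf: OpenReadingFrame, pam: PamSpec, flank5: str, flank3: str
) -> list[tuple[GuideSite, int]]:
    """Scan flank5+ORF+flank3 and shift coordinates into the ORF frame."""
    full = flank5 + orf.sequence + flank3
    offset = len(flank5)
    shifted = []
    for g in scan_pams(full, pam):
        site = GuideSite(
            protospacer=g.protospacer,
            pam=g.pam,
            strand=g.strand,
            start=g.start - offset,
            end=g.end - offset,
            frame_phase=(g.start - offset - 1) % 3,
        )
        shifted.append((site, offset))
    return shifted


def find_stop_guides(
    orf: OpenReadingFrame,
    pam: PamSpec = PamSpec("NGG"),
    window: EditingWindow = DEFAULT_WINDOW,
    flank5: str = "",
    flank3: str = "",
) -> list[GuideReport]:
    """All guides able to introduce a premature stop codon into *orf*.

    Both strands are searched: sense guides convert CAA/CAG/CGA to a stop
    directly (C->T on the coding strand), antisense guides convert TGG via
    G->A on the coding strand (TGG->TAG, TGG->TGA, or the double-edit
    TGG->TAA). One report is emitted per (guide site, stop-gain codon);
    the primary outcome uses the minimal edit subset reaching the stop and
    every other window C is summarized as a bystander. Optional flanking
    sequence lets guides extend past the ORF boundary; window Cs landing
    in flanks carry no codon annotation and are reported as bystanders of
    unknown consequence.
    """
    reports: list[GuideReport] = []
    for site, _ in _scan_orf_sites(orf, pam, flank5, flank3):
        cytosines = editable_cytosines(site, window, orf)
        in_orf = [c for c in cytosines if c.codon_index is not None]
        by_codon: dict[int, list[EditableCytosine]] = {}
        for c in in_orf:
            by_codon.setdefault(c.codon_index, []).append(c)
        for codon_index in sorted(by_codon):
            if orf.codon(codon_index) in STOP_CODONS:
                continue
            subsets = _codon_target_subsets(
                orf, codon_index, by_codon[codon_index],
                accept=lambda m: m in STOP_CODONS,
            )
            if subsets:
                reports.append(
                    _build_report(orf, site, cytosines, codon_index,
                                  _best_subset(subsets))
                )
    return reports


def _reachable_codons(codon: str) -> list[tuple[str, str]]:
    """All (mutated_codon, chemistry) pairs reachable from *codon* by a
    non-empty set of C->T (sense) or G->A (antisense) conversions."""
    out = []
    for base_from, base_to, chem in (("C", "T", "C>T"), ("G", "A", "G>A")):
        positions = [i + 1 for i, b in enumerate(codon) if b == base_from]
        for r in range(1, len(positions) + 1):
            for subset in itertools.combinations(positions, r):
                mutated = _mutate_codon(codon, {p: base_to for p in subset})
                out.append((mutated, chem))
    return out


def find_substitution_guides(
    orf: OpenReadingFrame,
    codon_index: int,
    desired: str,
    pam: PamSpec = PamSpec("NGG"),
    window: EditingWindow = DEFAULT_WINDOW,
    flank5: str = "",
    flank3: str = "",
) -> list[GuideReport]:
    """Guides producing a specific codon or amino-acid change at *codon_index*.

    *desired* is either a 3-nt codon or a one-letter amino acid ('*' for
    stop). Raises :class:`SubstitutionUnreachableError` when deamination
    chemistry cannot produce the change at all — distinct from returning an
    empty list, which means the change is chemically reachable but no
    suitably placed PAM exists.
    """
    if not 1 <= codon_index <= orf.codon_count:
        raise SequenceError(
            f"codon index {codon_index} outside [1, {orf.codon_count}]"
        )
    desired = desired.upper()
    original = orf.codon(codon_index)
    if len(desired) == 3:
        def accept(m: str) -> bool:
            return m == desired
    elif len(desired) == 1 and (desired in set(GENETIC_CODE.values())):
        def accept(m: str) -> bool:
            return GENETIC_CODE[m] == desired
    else:
        raise SequenceError(f"desired change {desired!r} is neither a codon nor an amino acid")

    if not any(accept(m) for m, _ in _reachable_codons(original)):
        raise SubstitutionUnreachableError(
            f"{original} (codon {codon_index}) cannot reach {desired!r} by "
            "C->T or G->A conversion"
        )

    reports: list[GuideReport] = []
    for site, _ in _scan_orf_sites(orf, pam, flank5, flank3):
        cytosines = editable_cytosines(site, window, orf)
        in_codon = [c for c in cytosines if c.codon_index == codon_index]
        if not in_codon:
            continue
        subsets = _codon_target_subsets(orf, codon_index, in_codon, accept)
        if subsets:
            reports.append(
                _build_report(orf, site, cytosines, codon_index,
                              _best_subset(subsets))
            )
    return reports


def rank_guides(
    reports: list[GuideReport], requested_class: str = "nonsense"
) -> list[GuideReport]:
    """Stable sort: requested outcome class first, then fewer non-silent
    bystanders, then higher primary position score, then smaller start."""
    return sorted(
        reports,
        key=lambda r: (
            0 if r.primary_outcome.outcome_class == requested_class else 1,
            r.nonsilent_bystanders,
            -r.score,
            r.site.start,
        ),
    )
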