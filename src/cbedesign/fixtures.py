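"""Packaged ground truth and a seeded synthetic-ORF generator.

Two kinds of fixtures make every module testable without downloads:

* the twelve published crRNAs (zebrafish tumor-suppressor / oncogene
  targets) with their editor, PAM class, intended change, and — where
  chromatograms labeled individual bases — the set of edited-C distances
  reported for them;
* a deterministic generator that plants stop-gainable codons (CAA/CAG/CGA
  with a sense PAM, TGG with an antisense PAM) into a random ORF and
  returns the answer key, so the exactness of the guide search can be
  asserted across seeds.

Reported efficiencies are wet-lab measurements kept as provenance
metadata; nothing in the package treats them as recomputable truth.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .seqcore import IUPAC_SETS, GENETIC_CODE, OpenReadingFrame, SequenceError, STOP_CODONS

logger = logging.getLogger("cbedesign")

__all__ = [
    "PaperGuideRecord",
    "PlantedGuide",
    "paper_guides",
    "guide_context",
    "canonical_pam",
    "synthetic_orf",
]


@dataclass(frozen=True)
class PaperGuideRecord:
    """One published crRNA with its design metadata."""

    gene_label: str
    crrna: str
    pam_class: str
    editor: str
    intended_change: str
    #: distances of the Cs whose editing the source labeled per-base; empty
    #: where only an overall efficiency was printed (never inferred).
    reported_edited_distances: frozenset[int] = field(default_factory=frozenset)
    #: highest reported editing efficiency (%) — provenance metadata only.
    reported_max_efficiency_percent: float | None = None


_PAPER_GUIDES: tuple[PaperGuideRecord, ...] = (
    PaperGuideRecord("ctnnb1 (S33L)", "CTGGACTCAGGAATACACTC", "NGG", "BE4-gam",
                     "S33L", frozenset({15, 13}), 73.0),
    PaperGuideRecord("tek (Q94*)", "GGAGCTCCAGGTGACGGTAG", "NGG", "BE4-gam",
                     "Q94*", frozenset({14, 13}), 18.0),
    PaperGuideRecord("bap1 (Q273*)", "GACTCAGCAAGAATCAGGCC", "NGG", "BE4-gam",
                     "Q273*", frozenset(), 14.0),
    PaperGuideRecord("tp53 (Q21*)", "AGTATTCAGCCCCCAGGTGG", "NGG", "BE4-gam",
                     "Q21*", frozenset(), 73.0),
    PaperGuideRecord("tp53 (Q170*)", "CAATCAGCGAGCAAATTACA", "NGG", "BE4-gam",
                     "Q170*", frozenset(), 86.0),
    PaperGuideRecord("kras (E62K)", "CCTCCTGACCTGCAGTGTCC", "NGG", "ancBE4max",
                     "E62K", frozenset({17, 16}), 19.0),
    PaperGuideRecord("dmd (Q8*)", "CCACAGGACCAATGGGAGGA", "NGG", "ancBE4max",
                     "Q8*", frozenset(), 14.0),
    PaperGuideRecord("sod2 (Q145*)", "GCTGTTCAGGGCTCAGGCTG", "NGG", "ancBE4max",
                     "Q145*", frozenset(), 64.0),
    PaperGuideRecord("rb1 (W63*)", "TCTCCATGCATGATCACAGA", "NGG", "ancBE4max",
                     "W63*", frozenset({19, 17, 16}), 91.0),
    PaperGuideRecord("nras NAA (G13S)", "AACACCTCCTGCTCCCACAA", "NAA",
                     "ancBE4max-SpymacCas9", "G13S", frozenset(), 19.0),
    PaperGuideRecord("tp53 NAA (Q170*)", "ATCAGCGAGCAAATTACAGG", "NAA",
                     "ancBE4max-SpymacCas9", "Q170*", frozenset(), 16.0),
    PaperGuideRecord("cbl (W577*)", "AGTTCCAGTCTGGCATGTTG", "NGG", "BE4-gam",
                     "W577*", frozenset({16, 15}), 50.0),
)


def paper_guides() -> list[PaperGuideRecord]:
    """The twelve published crRNA records."""
    return list(_PAPER_GUIDES)


def canonical_pam(pattern: str) -> str:
    """A concrete PAM instance for an IUPAC pattern (N -> A, else the
    alphabetically first base the code allows)."""
    return "".join(
        "A" if ch == "N" else min(IUPAC_SETS[ch.upper()]) for ch in pattern
    )


def guide_context(record: PaperGuideRecord) -> str:
    """Protospacer + canonical PAM instance, a minimal scannable context.

    The source prints the crRNAs but not their genomic loci, so the flank
    is synthesized; tests built on these contexts assert window/position
    logic, never genome coordinates.
    """
    return record.crrna + canonical_pam(record.pam_class)


@dataclass(frozen=True)
class PlantedGuide:
    """Answer-key entry: one deliberately designable codon in a synthetic ORF."""

    codon_index: int
    strand: str
    target_codon: str
    pam_start: int  # forward-strand coordinate of the PAM's first base
    distances: tuple[int, ...]  # window distances of the stop-making C(s)


_NONSTOP_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
_SENSE_TARGETS = ("CAA", "CAG", "CGA")


def _write(seq: list[str], start: int, text: str) -> None:
    seq[start - 1 : start - 1 + len(text)] = list(text)


def _introduces_stop(seq: list[str], positions: range, codon_count: int) -> bool:
    touched = {(p - 1) // 3 + 1 for p in positions}
    for j in touched:
        if j >= codon_count:  # terminal stop codon is protected by bounds anyway
            continue
        codon = "".join(seq[3 * (j - 1) : 3 * j])
        if codon in STOP_CODONS:
            return True
    return False


def synthetic_orf(
    codon_count: int = 60,
    stop_gain_codon_rate: float = 0.1,
    pam_density: float = 0.05,
    seed: int = 0,
) -> tuple[OpenReadingFrame, list[PlantedGuide]]:
    """Random ORF with planted, discoverable stop-gain guide placements.

    The ORF starts with ATG, ends with TAA, and contains no other in-frame
    stop. ``stop_gain_codon_rate`` sets the fraction of codons carrying a
    planted design (alternating sense CAA/CAG/CGA and antisense TGG
    placements, each with its AGG / antisense-AGG PAM written at a window
    distance); ``pam_density`` adds incidental AGG codons elsewhere so the
    scan also meets unplanted PAMs. Deterministic for a given seed. When a
    placement cannot be fitted (crowded or short ORF) it is dropped with a
    logged notice, so the returned key may be shorter than requested.
    """
    if codon_count < 10:
        raise SequenceError("codon_count must be at least 10")
    if not (0 <= stop_gain_codon_rate <= 1 and 0 <= pam_density <= 1):
        raise SequenceError("rates must lie in [0, 1]")
    rng = random.Random(seed)
    length = 3 * codon_count
    codons = ["ATG"] + [
        rng.choice(_NONSTOP_CODONS) for _ in range(codon_count - 2)
    ] + ["TAA"]
    seq = list("".join(codons))
    reserved = [False] * (length + 1)  # 1-based occupancy
    key: list[PlantedGuide] = []

    def span_free(lo: int, hi: int) -> bool:
        return lo >= 4 and hi <= length - 3 and not any(reserved[lo : hi + 1])

    n_plants = round(stop_gain_codon_rate * codon_count)
    for k in range(n_plants):
        antisense = k % 2 == 1
        for _attempt in range(200):
            i = rng.randint(2, codon_count - 1)
            p = 3 * i - 2
            if antisense:
                q = p - 16  # puts the TGG guanines at window distances 16 and 15
                lo, hi = q, q + 22
                if not span_free(lo, hi):
                    continue
                backup = seq[lo - 1 : hi]
                _write(seq, p, "TGG")
                _write(seq, q, "CCT")
                if _introduces_stop(seq, range(lo, hi + 1), codon_count):
                    seq[lo - 1 : hi] = backup
                    continue
                plant = PlantedGuide(i, "-", "TGG", pam_start=q, distances=(16, 15))
            else:
                target = rng.choice(_SENSE_TARGETS)
                d = rng.randint(13, 19)
                pam_start = p + d
                lo, hi = pam_start - 20, pam_start + 2
                if not span_free(lo, hi):
                    continue
                backup = seq[lo - 1 : hi]
                _write(seq, p, target)
                _write(seq, pam_start, "AGG")
                if _introduces_stop(seq, range(lo, hi + 1), codon_count):
                    seq[lo - 1 : hi] = backup
                    continue
                plant = PlantedGuide(i, "+", target, pam_start=pam_start, distances=(d,))
            for pos in range(lo, hi + 1):
                reserved[pos] = True
            key.append(plant)
            break
        else:
            logger.info(
                "could not fit planted guide %d/%d in %d codons; dropped",
                k + 1, n_plants, codon_count,
            )
    # incidental PAMs in untouched codons (AGG codes for Arg: no stop risk)
    for j in range(2, codon_count):
        lo, hi = 3 * j - 2, 3 * j
        if rng.random() < pam_density and not any(reserved[lo : hi + 1]):
            _write(seq, lo, "AGG")
    key.sort(key=lambda g: g.codon_index)
    return OpenReadingFrame("".join(seq)), key
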