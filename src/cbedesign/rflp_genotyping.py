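"""Restriction-digest (RFLP) prediction for genotyping base-edited alleles.

Because a C->T conversion can destroy (or create) an enzyme recognition
site, digesting a PCR amplicon often discriminates the wild-type and
edited alleles on a gel. This module predicts the fragment pattern of a
linear amplicon for a given enzyme and decides whether two alleles are
distinguishable at gel resolution.

The cut model is deliberately minimal: each recognition site maps to a
single top-strand cut coordinate (sticky ends are irrelevant to fragment
lengths on a gel). A cut coordinate p means "cut between p and p+1". For a
top-strand site starting at s, p = s + len(recognition) - 1 + cut_offset;
a bottom-strand site mirrors to p = s - cut_offset - 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .seqcore import SequenceError, iupac_match, iupac_revcomp, IUPAC_SETS

logger = logging.getLogger("cbedesign")

__all__ = [
    "RestrictionEnzyme",
    "DigestResult",
    "AssayVerdict",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "load_enzymes",
    "find_sites",
    "digest",
    "differential_assay",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """name, IUPAC recognition sequence, and top-strand cut offset.

    ``cut_offset`` counts nt downstream of the recognition 3' end on the
    strand carrying the match (0 = cut immediately after the site; negative
    offsets cut inside it). Offset conventions vary between catalogs, so
    user overrides are first-class.
    """

    name: str
    recognition: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise SequenceError(f"recognition {rec!r} shorter than 4 nt")
        for ch in rec:
            if ch not in IUPAC_SETS:
                raise SequenceError(f"unknown IUPAC code {ch!r} in recognition")

    @property
    def palindromic(self) -> bool:
        return self.recognition == iupac_revcomp(self.recognition)


#: Minimal built-in table; BsrI is the enzyme used for cbl genotyping.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("BsrI", "ACTGG", 1),
        RestrictionEnzyme("EcoRI", "GAATTC", -5),
        RestrictionEnzyme("BamHI", "GGATCC", -5),
        RestrictionEnzyme("HindIII", "AAGCTT", -5),
        RestrictionEnzyme("TaqI", "TCGA", -3),
    )
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise SequenceError(
            f"unknown enzyme {name!r}; built-ins: {', '.join(sorted(BUILTIN_ENZYMES))}. "
            "Supply a TSV enzyme table for others."
        ) from None


def load_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Read a tab-separated enzyme table: name, recognition, cut_offset."""
    table: dict[str, RestrictionEnzyme] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise SequenceError(
                    f"enzyme table row {row!r} needs 3 columns: name, recognition, cut_offset"
                )
            name, rec, off = row
            table[name] = RestrictionEnzyme(name, rec, int(off))
    return table


@dataclass(frozen=True)
class DigestResult:
    """Ordered fragment lengths (left to right) of a linear digest."""

    fragments: tuple[int, ...]
    site_count: int

    @property
    def total(self) -> int:
        return sum(self.fragments)


def find_sites(amplicon: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut coordinates for all recognition matches on both strands.

    Non-palindromic enzymes are matched on the bottom strand via the
    reverse complement of the recognition pattern, mapped back to
    top-strand coordinates. Duplicate coordinates are merged; cuts falling
    outside [1, len-1] are skipped with a logged notice.
    """
    m = len(enzyme.recognition)
    n = len(amplicon)
    patterns = [(enzyme.recognition, "+")]
    if not enzyme.palindromic:
        patterns.append((iupac_revcomp(enzyme.recognition), "-"))
    cuts: set[int] = set()
    for pattern, strand in patterns:
        for s in range(1, n - m + 2):
            if not iupac_match(pattern, amplicon[s - 1 : s + m - 1]):
                continue
            if strand == "+":
                p = s + m - 1 + enzyme.cut_offset
            else:
                p = s - enzyme.cut_offset - 1
            if 1 <= p <= n - 1:
                cuts.add(p)
            else:
                logger.info(
                    "%s site at %d cuts at %d, outside the amplicon; skipped",
                    enzyme.name, s, p,
                )
    return sorted(cuts)


def digest(amplicon: str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Fragment lengths of the linear amplicon after complete digestion."""
    if len(amplicon) < len(enzyme.recognition):
        raise SequenceError("amplicon shorter than the recognition sequence")
    cuts = find_sites(amplicon, enzyme)
    bounds = [0, *cuts, len(amplicon)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments=fragments, site_count=len(cuts))


@dataclass(frozen=True)
class AssayVerdict:
    distinguishable: bool
    wt: DigestResult
    edited: DigestResult
    resolution: int


def differential_assay(
    wt: str,
    edited: str,
    enzyme: RestrictionEnzyme,
    resolution: int = 20,
) -> AssayVerdict:
    """Decide whether *enzyme* discriminates the two alleles on a gel.

    The alleles must be equal length (base editing preserves length). Both
    fragment patterns are sorted by size and compared band against band
    (the shorter pattern padded with zero-length phantom bands); the assay
    is called distinguishable when at least one pair differs by more than
    *resolution* bp — 20 bp by default, a realistic agarose-gel limit for
    the fragment sizes involved.
    """
    if len(wt) != len(edited):
        raise SequenceError(
            f"allele lengths differ ({len(wt)} vs {len(edited)}); "
            "base editing preserves amplicon length"
        )
    wt_res = digest(wt, enzyme)
    ed_res = digest(edited, enzyme)
    a = sorted(wt_res.fragments, reverse=True)
    b = sorted(ed_res.fragments, reverse=True)
    width = max(len(a), len(b))
    a += [0] * (width - len(a))
    b += [0] * (width - len(b))
    distinguishable = any(abs(x - y) > resolution for x, y in zip(a, b))
    return AssayVerdict(
        distinguishable=distinguishable, wt=wt_res, edited=ed_res, resolution=resolution
    )
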