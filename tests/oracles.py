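"""Independent brute-force oracles used by the test suite.

Everything here is deliberately re-derived from first principles (simple
per-character loops, exhaustive enumeration) and shares no code with the
package, so agreement between the two is evidence, not tautology.
"""

import itertools

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_a + _b + _c] = _AAS[_i]


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def match(pattern, window):
    return len(pattern) == len(window) and all(
        (b == "N" and p == "N") or (b != "N" and b in _IUPAC[p])
        for p, b in zip(pattern, window)
    )


def brute_scan(seq, pam_pattern, proto_len=20):
    """Every protospacer+PAM placement on both strands, as a set of
    (strand, forward-strand protospacer start, protospacer, pam)."""
    hits = set()
    n, plen = len(seq), len(pam_pattern)
    for s0 in range(n - proto_len - plen + 1):
        if match(pam_pattern, seq[s0 + proto_len : s0 + proto_len + plen]):
            hits.add(("+", s0 + 1, seq[s0 : s0 + proto_len],
                      seq[s0 + proto_len : s0 + proto_len + plen]))
    rev = rc(seq)
    for s0 in range(n - proto_len - plen + 1):
        if match(pam_pattern, rev[s0 + proto_len : s0 + proto_len + plen]):
            # protospacer occupies rev[s0 : s0+proto_len]; its forward-strand
            # start is n - (s0 + proto_len) + 1
            hits.add(("-", n - s0 - proto_len + 1, rev[s0 : s0 + proto_len],
                      rev[s0 + proto_len : s0 + proto_len + plen]))
    return hits


def stop_reachable_codons(base_from, base_to):
    """Non-stop codons from which some subset of base_from->base_to changes
    yields a stop codon, by exhaustive enumeration."""
    stops = {c for c, aa in _CODE.items() if aa == "*"}
    reachable = set()
    for codon in _CODE:
        if codon in stops:
            continue
        positions = [i for i, b in enumerate(codon) if b == base_from]
        for r in range(1, len(positions) + 1):
            for subset in itertools.combinations(positions, r):
                mutated = "".join(
                    base_to if i in subset else b for i, b in enumerate(codon)
                )
                if mutated in stops:
                    reachable.add(codon)
    return reachable


def brute_cut_sites(amplicon, recognition, cut_offset):
    """Sliding-window recognition on both strands, mapped to top-strand cut
    coordinates with the package's stated convention; in-range, deduplicated."""
    m, n = len(recognition), len(amplicon)
    rec_rc = rc(recognition)
    cuts = set()
    for s0 in range(n - m + 1):
        window = amplicon[s0 : s0 + m]
        if window == recognition:
            cuts.add(s0 + m + cut_offset)
        if window == rec_rc and recognition != rec_rc:
            cuts.add(s0 - cut_offset)
    return sorted(p for p in cuts if 1 <= p <= n - 1)
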