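# Methods

## Editing model

`cbedesign` models a cytidine base editor as a deterministic chemistry
acting on a fixed geometry:

* **Geometry.** A guide is a 20-nt protospacer immediately 5′ of a PAM
  match (IUPAC pattern, default `NGG`). Cytosine distances are counted
  upstream of the PAM with the PAM-proximal protospacer base at d = 1, so
  protospacer 5′→3′ index = 21 − d. The editable window is the closed
  interval [d_min, d_max] = [13, 19] by default, identical for all PAM
  variants; both bounds are parameters (`EditingWindow`) because editor
  fusions differ in deaminase reach.
* **Chemistry.** The only primitive is C→T on the protospacer strand.
  For a guide on the coding (+) strand this is a coding C→T; for an
  antisense (−) guide the protospacer C pairs a coding-strand G, so the
  observed coding change is G→A. No other substitutions, and no indels,
  are modeled (the editors this targets produce essentially none).
* **Consequences.** Exhaustively over the 64 codons, a stop codon (TAA,
  TAG, TGA — standard genetic code via biopython's table) is reachable
  from exactly {CAA, CAG, CGA} by sense editing and {TGG} by antisense
  editing; the test suite re-derives these sets by brute force. For TGG
  the three stop outcomes (TAG, TGA, TAA) correspond to editing the
  second G, the third G, or both.

Per-molecule deamination is treated as all-or-none per cytosine: a guide
with k window cytosines yields 2^k possible haplotypes, all enumerated
(k ≤ 7 in the default window, so at most 128 subsets — exact enumeration,
no sampling). Cytosines sharing a codon are always evaluated on the
jointly mutated codon. Outcome-class precedence is
nonsense > mixed > missense > silent > none, because the stop is the
functional readout a knockout design cares about; silent co-edits are
still listed.

## Guide search and reporting

`scan_pams` reports every protospacer+PAM placement on both strands,
including overlapping PAMs and duplicate protospacer sequences (the
latter logged as non-unique); order is by forward-strand start, `+`
before `−`. `find_stop_guides` emits one report per (site, stop-gainable
codon). The **primary outcome** uses the minimal edit subset that reaches
the stop, ties broken by higher mean position score, then by more
PAM-distal distances for determinism; all other window Cs are summarized
as single-edit bystanders. `find_substitution_guides` runs the same
machinery with an arbitrary target codon or amino acid, and distinguishes
"chemically unreachable" (an exception — no subset of C→T/G→A edits can
ever produce the change) from "reachable but no PAM in range" (an empty
list).

Stop-gain searching is deliberately **not** strand-symmetric: the sense
stop-gain codons {CAA, CAG, CGA} reverse-complement to {TTG, CTG, TCG},
none of which is TGG, so mirroring the input changes which codons are
designable. Strand symmetry holds — and is property-tested — at the PAM
scan level, where the site set of the reverse complement is exactly the
mirrored site set.

### Position score

Editing efficiency peaks near the middle of the window and is
undetectable at d ≤ 12. The default score is the triangular

    s(d) = max(0, 1 − |d − 16| / 4)

giving s(16) = 1, s(13) = s(19) = 0.25, s(12) = s(20) = 0. It is a
ranking heuristic, not a calibrated efficiency model, and any callable
can replace it. A report's score is the mean of s(d) over the primary
edit subset (single-C primaries, the common case, are unaffected by the
choice of aggregate).

### Ranking

Stable sort by (1) requested outcome class first, (2) fewer non-silent
bystanders, (3) higher primary position score, (4) smaller start
coordinate. "Non-silent" counts missense/nonsense/unknown bystanders;
silent co-edits are free.

## Coordinates, frames, degenerate inputs

All coordinates are 1-based inclusive on the forward strand of the
input. ORFs must be a multiple of 3; a non-ATG start warns but proceeds
(partial ORFs are legitimate). N is accepted in sequence input, matches
only pattern code N during IUPAC matching (an unknown base cannot be
trusted to satisfy a narrower code), and translates to X rather than
failing a run. Guides whose window reaches past the ORF need explicit
flanking sequence (`flank5`/`flank3`); window Cs landing in flanks carry
no codon annotation and surface as bystanders of unknown consequence.

## RFLP genotyping

A restriction enzyme is (name, IUPAC recognition, cut_offset), where
cut_offset counts nt downstream of the recognition 3′ end on the strand
carrying the match. Each site maps to a **single top-strand cut
coordinate** (p = cut between p and p+1): s + len(rec) − 1 + offset for a
top-strand site at s, mirrored to s − offset − 1 for a bottom-strand
site. Sticky ends are not modeled because gel fragment length is the only
observable used. Fragments of a linear amplicon are the inter-cut
intervals; cuts falling outside [1, len−1] are skipped with a notice.
Offset conventions vary between catalogs, so the built-in table (BsrI
`ACTGG`+1, plus a few common enzymes) is overridable via a 3-column TSV.
Two alleles are called distinguishable when, after sorting both fragment
lists by size (shorter list padded with zero-length phantom bands), some
pair differs by more than the resolution parameter — default 20 bp, a
realistic agarose-gel limit at these sizes. Circular templates and
partial digestion are out of scope.

## Synthetic data

`synthetic_orf(codon_count=60, stop_gain_codon_rate=0.1, pam_density=0.05,
seed)` builds a random ORF (ATG start, TAA end, no internal stop) and
plants discoverable designs: alternating sense placements (a CAA/CAG/CGA
codon with an AGG PAM written at a uniformly drawn window distance) and
antisense placements (a TGG codon with its antisense-AGG PAM placed so
the two guanines sit at distances 16 and 15). Defaults: 60 codons keeps
the exhaustive scan instant while leaving room for ~6 non-overlapping
plants; a 10% plant rate and 5% incidental-PAM density give each run both
planted and unplanted hits, which is what the recovery and round-trip
properties need. The generator is deterministic per seed; placements that
cannot be fitted are dropped with a notice, so the answer key is a
guaranteed-present subset, and recovery is asserted as key ⊆ found.

What the generator emulates: PAM-adjacent designable codons on both
strands at controlled window distances. What it does not: real codon
usage, GC structure, repeats, or editing-efficiency variation — so
passing tests demonstrate the search is exact on the stated geometry, not
that any particular locus will edit efficiently in vivo.

## Known limitations

* Efficiency is a ranking heuristic only; measured per-base efficiencies
  shipped with the crRNA fixtures are provenance metadata, never truth.
* No off-target/specificity scoring; use a dedicated tool for that.
* Protospacer length is fixed at 20 nt; adenine base editors and
  alternative genetic codes are out of scope.
* Haplotype frequencies are enumerated, not inferred: per-C efficiencies
  are marginal measurements and carry no linkage information.
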