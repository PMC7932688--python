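import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from cbedesign import (
    EditingWindow,
    OpenReadingFrame,
    PamSpec,
    SequenceError,
    SubstitutionUnreachableError,
    editable_cytosines,
    find_stop_guides,
    find_substitution_guides,
    position_score,
    rank_guides,
    scan_pams,
)
from cbedesign.edit_outcomes import apply_edits
from cbedesign.guide_design import GuideReport, GuideSite, _best_subset  # noqa: F401

NGG = PamSpec("NGG")

dna = st.text(alphabet="ACGT", min_size=23, max_size=120)


def _site_key(sites):
    return {(g.strand, g.start, g.protospacer, g.pam) for g in sites}


class TestScanPams:
    def test_single_published_protospacer_with_adjacent_pam(self):
        sites = scan_pams("TCTCCATGCATGATCACAGA" + "AGG", NGG)
        assert len(sites) == 1
        (site,) = sites
        assert site.protospacer == "TCTCCATGCATGATCACAGA"
        assert (site.strand, site.start, site.end, site.pam) == ("+", 1, 20, "AGG")

    def test_no_pam_no_sites(self):
        assert scan_pams("A" * 23, NGG) == []

    def test_too_short_sequence_yields_empty_list(self):
        assert scan_pams("ACGTACGT", NGG) == []

    def test_overlapping_pams_give_distinct_sites(self):
        # NGGG contains two NGG matches -> two sites, one per PAM placement
        seq = "T" * 21 + "AGGG"
        sites = scan_pams(seq, NGG)
        plus = [g for g in sites if g.strand == "+"]
        assert len(plus) == 2
        assert {g.pam for g in plus} == {"AGG", "GGG"}

    def test_duplicate_protospacers_all_reported(self):
        unit = "ACGTACGTACGTACGTACGT" + "AGG"
        sites = scan_pams(unit + unit, NGG)
        dup = [g for g in sites if g.protospacer == "ACGTACGTACGTACGTACGT"]
        assert len(dup) == 2

    @pytest.mark.parametrize("pattern", ["NGG", "NAA"])
    def test_matches_bruteforce_oracle_on_random_sequence(self, pattern):
        rng = random.Random(11)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(200))
            assert _site_key(scan_pams(seq, PamSpec(pattern))) == oracles.brute_scan(
                seq, pattern
            )

    def test_output_ordered_by_start_plus_before_minus(self):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        sites = scan_pams(seq, NGG)
        keys = [(g.start, 0 if g.strand == "+" else 1) for g in sites]
        assert keys == sorted(keys)

    @given(dna)
    def test_strand_symmetry_of_scan(self, seq):
        """Scanning the reverse complement yields the mirrored site set."""
        n = len(seq)
        mirrored = {
            ("-" if strand == "+" else "+", n - start - 20 + 2, proto, pam)
            for strand, start, proto, pam in oracles.brute_scan(seq, "NGG")
        }
        assert _site_key(scan_pams(oracles.rc(seq), NGG)) == mirrored


class TestEditableCytosines:
    @pytest.mark.parametrize(
        "crrna, expected",
        [
            ("TCTCCATGCATGATCACAGA", [19, 17, 16]),  # rb1
            ("AGTTCCAGTCTGGCATGTTG", [16, 15]),      # cbl
            ("CTGGACTCAGGAATACACTC", [15, 13]),      # ctnnb1
            ("GGAGCTCCAGGTGACGGTAG", [16, 14, 13]),  # tek
            ("CCTCCTGACCTGCAGTGTCC", [19, 17, 16]),  # kras
            ("G" * 20, []),                           # no window C at all
        ],
    )
    def test_window_distances_of_published_guides(self, crrna, expected):
        (site,) = [
            g for g in scan_pams(crrna + "AGG", NGG) if g.strand == "+" and g.start == 1
        ]
        assert [c.d for c in editable_cytosines(site)] == expected

    def test_distance_index_identity(self):
        (site,) = [
            g
            for g in scan_pams("TCTCCATGCATGATCACAGAAGG", NGG)
            if g.strand == "+" and g.start == 1
        ]
        for c in editable_cytosines(site, EditingWindow(1, 20)):
            assert c.protospacer_index + c.d == 21
            assert site.protospacer[c.protospacer_index - 1] == "C"

    def test_window_bounds_validated(self):
        with pytest.raises(SequenceError):
            EditingWindow(0, 19)
        with pytest.raises(SequenceError):
            EditingWindow(14, 13)


class TestPositionScore:
    @pytest.mark.parametrize(
        "d, score", [(16, 1.0), (12, 0.0), (13, 0.25), (19, 0.25), (20, 0.0), (1, 0.0)]
    )
    def test_triangular_profile(self, d, score):
        assert position_score(d) == pytest.approx(score)


class TestFindStopGuides:
    def test_toy_orf_single_sense_stop_gain(self, toy_stop_orf):
        reports = find_stop_guides(toy_stop_orf)
        assert len(reports) == 1
        (r,) = reports
        assert (r.site.strand, r.site.start) == ("+", 1)
        assert r.target_codon == 2
        assert r.primary_change == "Q2*"
        assert r.primary_outcome.codon_changes[0].alt_codon == "TAA"
        assert [c.d for c in r.primary_outcome.edited] == [17]

    def test_orf_with_only_missense_windows_yields_nothing(self, ctnnb1_like_orf):
        assert find_stop_guides(ctnnb1_like_orf) == []

    def test_antisense_tgg_stop_gain(self, cbl_like_orf):
        reports = find_stop_guides(cbl_like_orf)
        tgg = [r for r in reports if r.target_codon == 8]
        assert tgg, "in-frame TGG with both guanines in-window must be found"
        (r,) = tgg
        assert r.site.strand == "-"
        assert r.site.protospacer == "AGTTCCAGTCTGGCATGTTG"
        assert r.primary_outcome.outcome_class == "nonsense"
        # minimal subset: a single edit already creates TAG or TGA
        assert len(r.primary_outcome.edited) == 1

    def test_stop_gain_codon_sets_match_exhaustive_oracle(self):
        assert oracles.stop_reachable_codons("C", "T") == {"CAA", "CAG", "CGA"}
        assert oracles.stop_reachable_codons("G", "A") == {"TGG"}

    def test_stop_search_is_frame_aware_not_strand_symmetric(self, toy_stop_orf):
        """Stop-gains depend on the reading frame: the mirrored input has no
        antisense-editable TGG where the original had a sense CAA."""
        mirrored = OpenReadingFrame(oracles.rc(toy_stop_orf.sequence))
        assert find_stop_guides(toy_stop_orf) != []
        assert find_stop_guides(mirrored) == []

    def test_every_reported_stop_verified_by_roundtrip(self):
        from cbedesign import synthetic_orf

        for seed in range(5):
            orf, _ = synthetic_orf(seed=seed)
            for r in find_stop_guides(orf):
                edited = apply_edits(orf, r.primary_outcome)
                assert edited.protein()[r.target_codon - 1] == "*"

    def test_flanking_sequence_enables_boundary_guides(self):
        # CAA at the final coding codon: the PAM must sit in 3' flank
        orf = OpenReadingFrame("ATG" + "GAT" * 5 + "CAA")
        assert find_stop_guides(orf) == []
        flank3 = "T" * 14 + "AGG" + "T" * 5
        reports = find_stop_guides(orf, flank3=flank3)
        assert any(r.target_codon == 7 and r.primary_change == "Q7*" for r in reports)


class TestFindSubstitutionGuides:
    def test_ser_to_leu_via_d13(self, ctnnb1_like_orf):
        reports = find_substitution_guides(ctnnb1_like_orf, 4, "L")
        assert len(reports) == 1
        (r,) = reports
        assert r.primary_change == "S4L"
        assert r.primary_outcome.codon_changes[0].alt_codon == "TTA"
        assert [c.d for c in r.primary_outcome.edited] == [13]
        assert [(b.d, b.outcome_class) for b in r.bystanders] == [(15, "silent")]

    def test_desired_codon_form_accepted(self, ctnnb1_like_orf):
        reports = find_substitution_guides(ctnnb1_like_orf, 4, "TTA")
        assert [r.primary_change for r in reports] == ["S4L"]

    def test_non_deamination_change_is_unreachable(self, ctnnb1_like_orf):
        # ATG can only reach ATA (G->A); Val needs a transversion or A->G,
        # which deamination chemistry cannot perform
        with pytest.raises(SubstitutionUnreachableError):
            find_substitution_guides(ctnnb1_like_orf, 1, "V")

    def test_unreachable_is_distinct_from_no_pam(self):
        # TCA->TTA is chemically reachable, but this ORF offers no PAM
        orf = OpenReadingFrame("ATG" + "TCA" + "AAT" * 6)
        assert find_substitution_guides(orf, 2, "L") == []

    def test_stop_request_matches_stop_search(self, cag_stop_orf):
        stops = [r for r in find_stop_guides(cag_stop_orf) if r.target_codon == 2]
        subs = find_substitution_guides(cag_stop_orf, 2, "*")
        assert [(r.site, r.primary_outcome) for r in subs] == [
            (r.site, r.primary_outcome) for r in stops
        ]


class TestRankGuides:
    def _report(self, outcome_class, n_bystanders, score, start):
        from cbedesign.edit_outcomes import EditOutcome
        from cbedesign.guide_design import Bystander

        site = GuideSite("A" * 20, "AGG", "+", start, start + 19)
        outcome = EditOutcome(edited=(), codon_changes=(), outcome_class=outcome_class)
        bystanders = tuple(
            Bystander(d=14, outcome_class="missense", codon_change="", protein_change="")
            for _ in range(n_bystanders)
        )
        return GuideReport(
            site=site, editable=(), target_codon=1, primary_outcome=outcome,
            bystanders=bystanders, score=score,
        )

    def test_fewer_nonsilent_bystanders_first(self):
        a = self._report("nonsense", 0, 0.5, 100)
        b = self._report("nonsense", 2, 0.5, 1)
        assert rank_guides([b, a]) == [a, b]

    def test_higher_position_score_first(self):
        near = self._report("nonsense", 0, 1.0, 100)   # d=16 primary
        edge = self._report("nonsense", 0, 0.25, 1)    # d=13 primary
        assert rank_guides([edge, near]) == [near, edge]

    def test_requested_class_first_then_stable_coordinate_tiebreak(self):
        miss = self._report("missense", 0, 1.0, 1)
        non1 = self._report("nonsense", 0, 0.5, 7)
        non2 = self._report("nonsense", 0, 0.5, 3)
        assert rank_guides([miss, non1, non2]) == [non2, non1, miss]
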