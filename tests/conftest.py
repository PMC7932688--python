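import pytest
from hypothesis import HealthCheck, settings

from cbedesign import OpenReadingFrame

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_stop_orf():
    """27-nt ORF with one sense stop-gainable codon (CAA at codon 2) and an
    AGG PAM placed so the target C sits at window distance 17."""
    return OpenReadingFrame("atgcaagatgatgatgatgaaggttaa")


@pytest.fixture
def cag_stop_orf():
    """Like toy_stop_orf but with CAG at codon 2 (Q-to-stop via CAG->TAG)."""
    return OpenReadingFrame("ATGCAGGATGATGATGATGAAGGTTAA")


@pytest.fixture
def ctnnb1_like_orf():
    """ORF embedding the beta-catenin S33L-style guide on the sense strand:
    codons ATG CTG GAC TCA GGA ATA CAC TCA GGT TAA, protospacer at nt 4-23
    (CTGGACTCAGGAATACACTC) with AGG PAM at 24-26. The window C at d=15 is
    the third base of GAC (silent GAC>GAT), the one at d=13 the second base
    of TCA (missense S->L)."""
    return OpenReadingFrame("ATGCTGGACTCAGGAATACACTCAGGTTAA")


@pytest.fixture
def cbl_like_orf():
    """ORF embedding the cbl W577*-style guide on the antisense strand:
    codons ATG AAC CTC AAC ATG CCA GAC TGG AAC TAA. The reverse complement
    of nt 9-28 equals the published cbl protospacer AGTTCCAGTCTGGCATGTTG,
    with its (antisense) AGG PAM at nt 6-8 (CCT on the coding strand). The
    in-frame TGG at codon 8 carries both editable guanines at window
    distances 16 and 15."""
    return OpenReadingFrame("ATGAACCTCAACATGCCAGACTGGAACTAA")
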