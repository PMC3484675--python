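import pytest

from retrodate.gene_coords import GeneModel
from retrodate.synthetic import SimConfig, simulate_history


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    """A 60-nt two-exon gene: exon1 1-30, intron 31-40, exon2 41-60.

    Spliced transcript is 50 nt; 5' UTR of 10 nt, CDS of 30 nt
    (positions 11-40 spliced, ATG...TAA), 3' UTR of 10 nt.
    """
    exon1 = "GGGGGGGGGG" + "ATGAAACCCGGGTTTACGTA"  # utr5 + first 20 CDS nt
    intron = "GTCCCCCCAG"
    exon2 = "CTAGCATAA" + "T" + "CCCCCCCCCC"  # last 10 CDS nt + utr3
    # CDS spliced 11..40: ATGAAACCCGGGTTTACGTA + CTAGCATAAT is 30 nt
    seq = exon1 + intron + exon2
    return GeneModel("toy", seq, [(1, 30), (41, 60)], cds_start=11, cds_end=40)


@pytest.fixture(scope="session")
def default_bundle():
    """One deterministic synthetic history shared across tests."""
    return simulate_history(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)
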