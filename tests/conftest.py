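import pytest

from ribopause.reference_io import reverse_complement  # noqa: F401 (used in fixture)
from ribopause.synthetic_data import PlantedMotif, SimSpec


@pytest.fixture
def tiny_genome(tmp_path):
    """Two-record FASTA with a hand-built plus- and minus-strand gene."""
    # chrA: 10 nt pad + plus-strand CDS ATG CCG CCG AAA TAA + 10 nt pad
    cds = "ATGCCGCCGAAATAA"
    chra = "GGGGGGGGGG" + cds + "CCCCCCCCCC"
    # chrB: minus-strand copy of the same CDS at [5, 20)
    from ribopause.reference_io import reverse_complement
    chrb = "TTTTT" + reverse_complement(cds) + "AAAAA"
    path = tmp_path / "genome.fa"
    path.write_text(f">chrA\n{chra}\n>chrB\n{chrb}\n")
    return path, {"chrA": chra, "chrB": chrb}


@pytest.fixture
def small_sim_spec():
    """A fast synthetic study: 12 genes, 2 strong planted sites, 2 decoys."""
    planted = [
        PlantedMotif(0, "EPPK", 20, {"WT": 1.0, "delta_efp": 15.0,
                                     "complemented": 1.5}),
        PlantedMotif(1, "DPPN", 25, {"WT": 1.0, "delta_efp": 15.0,
                                     "complemented": 1.5}),
        PlantedMotif(2, "EPPK", 30, {"WT": 1.0, "delta_efp": 1.0,
                                     "complemented": 1.0}),
        PlantedMotif(3, "QPPS", 35, {"WT": 1.0, "delta_efp": 1.0,
                                     "complemented": 1.0}),
    ]
    return SimSpec(n_genes=12, gene_length_codons=(120, 200),
                   planted_motifs=planted, depth=30.0, replicates=2, seed=7)
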