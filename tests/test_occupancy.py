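"""Footprint assignment, codon binning, coverage gate, replicate stats."""

import numpy as np
import pytest

from ribopause.occupancy import (CodonOccupancy, OffsetRule, SampleTrack,
                                 assign_footprints, average_replicates,
                                 codon_occupancy, filter_covered,
                                 load_bedgraph, replicate_correlation,
                                 write_bedgraph)
from ribopause.reference_io import GeneRecord


def _gene(start, end, strand, seq_id="chr"):
    n = (end - start) // 3
    return GeneRecord("g", seq_id, start, end, strand,
                      "AAA" * n, "K" * (n - 1))


class TestOffsetRule:
    def test_center_rule(self):
        assert OffsetRule("center").position(100, 127, "+") == 113

    def test_three_prime_rule(self):
        assert OffsetRule("three_prime", 12).position(100, 127, "+") == 114
        assert OffsetRule("three_prime", 12).position(100, 127, "-") == 112

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            OffsetRule("p_site_magic")


class TestAssignFootprints:
    def test_sam_input_counts_and_skips(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:1000\n"
            "r1\t0\tchr\t101\t60\t27M\t*\t0\t0\t" + "A" * 27 + "\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"          # unmapped
            "r3\t256\tchr\t101\t60\t27M\t*\t0\t0\t" + "A" * 27 + "\t*\n")
        track = assign_footprints(sam, "s1")
        assert track.counts == {("chr", "+", 113): 1}
        assert track.n_skipped == 2

    def test_interval_tsv_input(self, tmp_path):
        p = tmp_path / "reads.tsv"
        p.write_text("chr\t100\t127\t+\nchr\t100\t127\t-\n")
        track = assign_footprints(p, "s1")
        assert track.counts[("chr", "+", 113)] == 1
        assert track.counts[("chr", "-", 113)] == 1


class TestCodonOccupancy:
    def test_plus_strand_binning(self):
        gene = _gene(0, 30, "+")
        track = SampleTrack("s", "WT")
        track.add("chr", "+", 3, 2)
        track.add("chr", "+", 4, 1)
        occ = codon_occupancy(track, gene)
        expected = np.zeros(10)
        expected[1] = 3
        assert np.array_equal(occ.reads_per_codon, expected)

    def test_uniform_coverage_conserved(self):
        gene = _gene(0, 30, "+")
        track = SampleTrack("s", "WT")
        for i in range(30):
            track.add("chr", "+", i)
        occ = codon_occupancy(track, gene)
        assert np.all(occ.reads_per_codon == 3)
        assert occ.gene_mean == 3

    def test_minus_strand_codon_one_at_genomic_three_prime(self):
        # minus-strand gene on [0,30): codon 1 occupies genomic [27,30)
        gene = _gene(0, 30, "-")
        track = SampleTrack("s", "WT")
        track.add("chr", "-", 29)  # first nt of the start codon
        occ = codon_occupancy(track, gene)
        # oracle: explicit reverse-complement index mapping
        assert occ.reads_per_codon[0] == 1
        assert occ.reads_per_codon[1:].sum() == 0

    def test_unstranded_counts_match_any_gene(self):
        gene = _gene(0, 30, "-")
        track = SampleTrack("s", "WT")
        track.add("chr", ".", 0)
        occ = codon_occupancy(track, gene)
        assert occ.reads_per_codon[-1] == 1  # genomic 5' end = last codon

    def test_offset_rule_invariance_on_uniform_data(self, tmp_path):
        reads = "".join(f"chr\t{s}\t{s+27}\t+\n" for s in range(0, 300))
        p = tmp_path / "reads.tsv"
        p.write_text(reads)
        gene = _gene(60, 240, "+")
        occs = []
        for rule in (OffsetRule("center"), OffsetRule("three_prime", 12)):
            occs.append(codon_occupancy(
                assign_footprints(p, "s", rule=rule), gene))
        assert np.array_equal(occs[0].reads_per_codon, occs[1].reads_per_codon)

    def test_normalized_mean_is_one(self):
        rng = np.random.default_rng(0)
        occ = CodonOccupancy("g", "s", rng.poisson(5.0, size=200).astype(float))
        assert abs(occ.normalized().mean() - 1.0) < 1e-9


class TestCoverageGate:
    @pytest.mark.parametrize("mean,expected", [
        (2.9, False),   # below the 3 reads/codon criterion
        (3.0, True),    # boundary inclusive
        (0.0, False),   # all-zero gene
    ])
    def test_threshold(self, mean, expected):
        occ = CodonOccupancy("g", "s", np.full(10, mean))
        assert filter_covered(occ) is expected


class TestReplicateStats:
    def test_identical_replicates_correlate_perfectly(self):
        a = {f"g{i}": float(10 + i) for i in range(50)}
        assert replicate_correlation(a, dict(a)) == pytest.approx(1.0)

    def test_independent_heavy_tailed_replicates_near_zero(self):
        rng = np.random.default_rng(42)
        a = {f"g{i}": v for i, v in enumerate(rng.lognormal(3, 2, 500))}
        b = {f"g{i}": v for i, v in enumerate(rng.lognormal(3, 2, 500))}
        assert abs(replicate_correlation(a, b)) < 0.2

    def test_too_few_shared_genes(self):
        with pytest.raises(ValueError):
            replicate_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    @pytest.mark.parametrize("values,mean,discordant", [
        ((10, 12), 11.0, False),
        ((7,), 7.0, False),
        ((0, 8), 4.0, True),     # zero vs positive: >5-fold disagreement
        ((1, 10), 5.5, True),
        ((2, 9), 5.5, False),
    ])
    def test_average_replicates(self, values, mean, discordant):
        res = average_replicates(values)
        assert res.mean == pytest.approx(mean)
        assert res.discordant is discordant

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            average_replicates([])


def test_bedgraph_roundtrip(tmp_path):
    track = SampleTrack("s", "WT")
    track.add("chr", "+", 5, 3)
    track.add("chr", "+", 9, 1)
    p = tmp_path / "t.bedgraph"
    write_bedgraph(track, p)
    loaded = load_bedgraph(p, "s")
    assert loaded.counts == {("chr", ".", 5): 3, ("chr", ".", 9): 1}
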