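"""Synthetic ribosome-profiling datasets with planted stall sites.

Generates a complete study — genome FASTA, CDS annotation, and
multi-strain, multi-replicate footprint tracks — in which ZPPX stall sites
of known strength are planted. Per-codon footprint counts follow a negative
binomial whose mean is depth x per-gene expression x codon dwell time; the
dwell time is a planted multiplier over the 3-codon stall window in the
stall condition (efp-deletion) and 1 elsewhere, and each codon's count is
spread multinomially over its 3 nucleotides. Everything is deterministic
under the spec seed.

For a planted multiplier m on a w=3 codon window of a gene with L codons,
the expected pausing index converges (deep coverage) to the closed form

    m / (1 + (w / L) * (m - 1))

because the gene mean itself includes the inflated window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .context_stats import CodonUsageTable
from .occupancy import SampleTrack
from .reference_io import (GeneRecord, GenomeSequence, translate,
                           write_annotation_gff3, write_genome)

PathLike = Union[str, Path]

STALL_WINDOW_CODONS = 3


@dataclass
class PlantedMotif:
    """A stall site planted into a synthetic gene.

    ``codon_position`` is the 1-based protein position of the first residue
    of ``motif`` (e.g. the Z of 'EPPK'); multipliers map condition name to
    the dwell-time multiplier over the (P-1, P_P, X_A) window.
    """

    gene_index: int
    motif: str
    codon_position: int
    multipliers: Dict[str, float]

    @property
    def first_p(self) -> int:
        """1-based protein position of the first proline."""
        return self.codon_position + self.motif.index("PP")

    @property
    def x_codon_index(self) -> int:
        return self.first_p + 2

    @property
    def window(self) -> Tuple[int, int, int]:
        return (self.first_p, self.first_p + 1, self.first_p + 2)


@dataclass
class SimSpec:
    """Full parameterization of a synthetic dataset."""

    n_genes: int = 200
    gene_length_codons: Tuple[int, int] = (250, 450)
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    planted_motifs: List[PlantedMotif] = field(default_factory=list)
    depth: float = 20.0
    dispersion: float = 10.0
    conditions: Tuple[str, ...] = ("WT", "delta_efp", "complemented")
    replicates: int = 2
    seed: int = 0
    minus_strand_fraction: float = 0.5
    spacer_length: int = 50
    rare_a_site_codons: bool = False


def default_sim_spec(seed: int = 0) -> SimSpec:
    """The default study: 200 genes, 30 strong planted sites (multiplier 15
    in the efp-deletion strain, restored to 1.5 in the complemented strain),
    100 neutral decoy PPX sites, depth 20 reads/codon, 2 replicates."""
    motifs = ["EPPK", "DPPN", "EPPD", "KPPQ", "NPPG", "QPPS"]
    planted = []
    for i in range(30):
        planted.append(PlantedMotif(
            gene_index=i, motif=motifs[i % len(motifs)],
            codon_position=40 + (i % 17) * 3,
            multipliers={"WT": 1.0, "delta_efp": 15.0, "complemented": 1.5}))
    for i in range(100):
        planted.append(PlantedMotif(
            gene_index=30 + i, motif=motifs[i % len(motifs)],
            codon_position=40 + (i % 23) * 3,
            multipliers={"WT": 1.0, "delta_efp": 1.0, "complemented": 1.0}))
    return SimSpec(planted_motifs=planted, seed=seed)


def expected_pausing_index(multiplier: float, n_codons: int,
                           window: int = STALL_WINDOW_CODONS) -> float:
    """Closed-form deep-coverage pausing index of a planted stall."""
    return multiplier / (1.0 + (window / n_codons) * (multiplier - 1.0))


_AA_NO_P = "ACDEFGHIKLMNQRSTVWY"  # prolines only where planted


def _max_codon_table(usage: CodonUsageTable, rare: bool = False) -> Dict[str, str]:
    """aa -> back-translation codon (highest-frequency, or rarest sense)."""
    best: Dict[str, Tuple[float, str]] = {}
    for codon, aa in usage.amino_acids.items():
        if aa == "*":
            continue
        freq = usage.frequencies[codon]
        cur = best.get(aa)
        better = (cur is None or
                  (freq < cur[0] if rare else freq > cur[0]))
        if better:
            best[aa] = (freq, codon)
    return {aa: codon for aa, (_f, codon) in best.items()}


def generate_reference(spec: SimSpec
                       ) -> Tuple[GenomeSequence, List[GeneRecord],
                                  List[PlantedMotif]]:
    """Random CDSs with the planted amino-acid motifs back-translated in.

    Proteins are drawn without incidental prolines so the PPX site list is
    exactly the planted truth; genes alternate between strands and are
    separated by random spacers. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    usage = CodonUsageTable.default()
    codon_of = _max_codon_table(usage)
    rare_codon_of = _max_codon_table(usage, rare=True)

    by_gene: Dict[int, List[PlantedMotif]] = {}
    for pm in spec.planted_motifs:
        by_gene.setdefault(pm.gene_index, []).append(pm)

    lo, hi = spec.gene_length_codons
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    minus = rng.random(spec.n_genes) < spec.minus_strand_fraction

    chrom_parts: List[str] = []
    genes: List[GeneRecord] = []
    cursor = 0
    for gi in range(spec.n_genes):
        n_aa = int(lengths[gi])
        protein = ["M"] + [
            _AA_NO_P[k] for k in rng.integers(0, len(_AA_NO_P), size=n_aa - 1)
        ]
        for pm in by_gene.get(gi, []):
            start = pm.codon_position - 1
            if start < 3 or start + len(pm.motif) >= n_aa:
                raise ValueError(
                    f"planted motif {pm.motif!r} at codon {pm.codon_position} "
                    f"does not fit gene {gi} of {n_aa} codons")
            protein[start:start + len(pm.motif)] = list(pm.motif)
        protein_str = "".join(protein)
        cds = "".join(codon_of[aa] for aa in protein_str)
        if spec.rare_a_site_codons:
            cds_list = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            for pm in by_gene.get(gi, []):
                xi = pm.x_codon_index - 1
                cds_list[xi] = rare_codon_of[protein_str[xi]]
            cds = "".join(cds_list)
        cds += "TAA"
        assert translate(cds) == protein_str

        spacer = "".join("ACGT"[k] for k in
                         rng.integers(0, 4, size=spec.spacer_length))
        chrom_parts.append(spacer)
        cursor += spec.spacer_length
        strand = "-" if minus[gi] else "+"
        genomic = cds
        if strand == "-":
            from .reference_io import reverse_complement
            genomic = reverse_complement(cds)
        chrom_parts.append(genomic)
        genes.append(GeneRecord(
            gene_id=f"gene{gi:04d}", seq_id="chrSim", start=cursor,
            end=cursor + len(cds), strand=strand, cds_nt=cds,
            protein=protein_str))
        cursor += len(cds)
    chrom_parts.append("".join("ACGT"[k] for k in
                               rng.integers(0, 4, size=spec.spacer_length)))
    genome = GenomeSequence({"chrSim": "".join(chrom_parts)})
    return genome, genes, spec.planted_motifs


def _dwell_profile(n_codons: int, motifs: Sequence[PlantedMotif],
                   condition: str) -> np.ndarray:
    dwell = np.ones(n_codons)
    for pm in motifs:
        m = pm.multipliers.get(condition, 1.0)
        for c in pm.window:  # 1-based codon indices
            dwell[c - 1] = max(dwell[c - 1], m)
    return dwell


def simulate_tracks(spec: SimSpec, genome: GenomeSequence,
                    genes: Sequence[GeneRecord]
                    ) -> Dict[Tuple[str, int], SampleTrack]:
    """Negative-binomial footprint tracks per condition per replicate.

    Per-codon count ~ NB(mean = depth x expression x dwell, size =
    dispersion); per-gene expression is log-normal and shared across
    conditions and replicates, so replicates differ only by counting noise.
    Counts are spread multinomially over each codon's 3 nucleotides.
    Returns a mapping (condition, replicate) -> SampleTrack.
    """
    rng_expr = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    expression = rng_expr.lognormal(spec.expression_mu, spec.expression_sigma,
                                    size=len(genes))
    by_gene: Dict[int, List[PlantedMotif]] = {}
    for pm in spec.planted_motifs:
        by_gene.setdefault(pm.gene_index, []).append(pm)

    tracks: Dict[Tuple[str, int], SampleTrack] = {}
    for ci, condition in enumerate(spec.conditions):
        for rep in range(1, spec.replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 101, ci, rep]))
            track = SampleTrack(sample_id=f"{condition}_rep{rep}",
                                strain=condition, replicate=rep)
            for gi, gene in enumerate(genes):
                n_codons = gene.n_codons
                dwell = _dwell_profile(n_codons, by_gene.get(gi, []),
                                       condition)
                mean = spec.depth * expression[gi] * dwell
                if spec.dispersion > 0:
                    # NB as gamma-Poisson; size = dispersion parameter
                    shape = spec.dispersion
                    lam = rng.gamma(shape, mean / shape)
                    counts = rng.poisson(lam)
                else:  # Poisson limit
                    counts = rng.poisson(mean)
                for c in np.nonzero(counts)[0]:
                    split = rng.multinomial(counts[c], [1 / 3] * 3)
                    for k in range(3):
                        if split[k] == 0:
                            continue
                        if gene.strand == "+":
                            pos = gene.start + 3 * c + k
                        else:
                            pos = gene.end - 1 - (3 * c + k)
                        track.add(gene.seq_id, gene.strand, int(pos),
                                  int(split[k]))
            tracks[(condition, rep)] = track
    return tracks


def write_truth_table(spec: SimSpec, genes: Sequence[GeneRecord],
                      path: PathLike) -> None:
    """Truth TSV: one row per planted site per condition."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmotif\tx_codon_index\tcondition\tmultiplier\n")
        for pm in spec.planted_motifs:
            gene_id = genes[pm.gene_index].gene_id
            for condition in spec.conditions:
                fh.write(f"{gene_id}\t{pm.motif}\t{pm.x_codon_index}\t"
                         f"{condition}\t{pm.multipliers.get(condition, 1.0)}\n")


def end_to_end_fixture(spec: SimSpec, out_dir: PathLike
                       ) -> Dict[str, Path]:
    """Write the full fixture: FASTA, GFF3, bedGraph tracks and truth table."""
    from .occupancy import write_bedgraph

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, _ = generate_reference(spec)
    tracks = simulate_tracks(spec, genome, genes)
    paths: Dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_genome(genome, paths["genome"])
    paths["annotation"] = out / "annotation.gff3"
    write_annotation_gff3(genes, paths["annotation"])
    for (condition, rep), track in tracks.items():
        key = f"track_{condition}_rep{rep}"
        paths[key] = out / f"{condition}_rep{rep}.bedgraph"
        write_bedgraph(track, paths[key])
    paths["truth"] = out / "truth.tsv"
    write_truth_table(spec, genes, paths["truth"])
    return paths
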