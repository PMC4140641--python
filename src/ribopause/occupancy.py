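"""Per-codon ribosome occupancy.

Converts footprint alignments (SAM/BAM or read-interval TSV) or precomputed
per-nucleotide coverage tracks (bedGraph/TSV) into per-codon counts per gene,
applies the read-coverage gate, and provides replicate statistics. Each
footprint contributes one count at a single nucleotide chosen by an offset
rule; counts are then summed in consecutive 3-nt bins along the coding
strand, so codon 1 of a minus-strand gene is the bin at the genomic 3' end.
Gene-level density is the arithmetic mean of the per-codon counts over the
whole ORF; occupancies are normalized by that mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np
from scipy import stats

from .reference_io import GeneRecord

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: default coverage gate, mean reads per codon over the ORF
DEFAULT_COVERAGE_THRESHOLD = 3.0

#: replicates whose values differ by more than this factor are flagged
REPLICATE_DISCORDANCE_FOLD = 5.0


class OffsetRule:
    """Footprint-to-nucleotide assignment rule.

    ``mode='center'`` places the count at the center nucleotide of the
    footprint, floor((start+end-1)/2) for a 0-based half-open interval.
    ``mode='three_prime'`` places it at a fixed offset upstream of the
    3' end (strand-aware).
    """

    def __init__(self, mode: str = "center", offset: int = 12):
        if mode not in {"center", "three_prime"}:
            raise ValueError(f"unknown offset rule {mode!r}")
        self.mode = mode
        self.offset = offset

    def position(self, start: int, end: int, strand: str) -> int:
        if self.mode == "center":
            return (start + end - 1) // 2
        if strand == "-":
            return start + self.offset
        return end - 1 - self.offset


@dataclass
class SampleTrack:
    """Per-nucleotide footprint counts for one sample.

    Keys are (seq_id, strand, position); strand '.' means unstranded and
    matches genes on either strand.
    """

    sample_id: str
    strain: str
    replicate: int = 1
    counts: Dict[Tuple[str, str, int], int] = field(default_factory=dict)
    n_skipped: int = 0

    def add(self, seq_id: str, strand: str, pos: int, n: int = 1) -> None:
        key = (seq_id, strand, pos)
        self.counts[key] = self.counts.get(key, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CodonOccupancy:
    """Per-codon footprint counts for one gene in one sample."""

    gene_id: str
    sample_id: str
    reads_per_codon: np.ndarray

    @property
    def gene_mean(self) -> float:
        return float(np.mean(self.reads_per_codon))

    def normalized(self) -> np.ndarray:
        """Occupancy divided by the gene mean (mean 1 for covered genes)."""
        mean = self.gene_mean
        if mean == 0:
            return np.zeros_like(self.reads_per_codon, dtype=float)
        return self.reads_per_codon / mean


def assign_footprints(path: PathLike, sample_id: str, strain: str = "custom",
                      replicate: int = 1,
                      rule: Optional[OffsetRule] = None) -> SampleTrack:
    """Build a SampleTrack from aligned footprints (SAM/BAM or interval TSV).

    Unmapped, secondary and supplementary alignments are skipped and tallied
    in ``track.n_skipped``.
    """
    rule = rule or OffsetRule()
    path = Path(path)
    track = SampleTrack(sample_id=sample_id, strain=strain, replicate=replicate)
    if path.suffix.lower() in {".sam", ".bam"}:
        import pysam

        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    track.n_skipped += 1
                    continue
                strand = "-" if aln.is_reverse else "+"
                pos = rule.position(aln.reference_start, aln.reference_end,
                                    strand)
                track.add(aln.reference_name, strand, pos)
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                seq_id, start, end, strand = line.split("\t")[:4]
                pos = rule.position(int(start), int(end), strand)
                track.add(seq_id, strand, pos)
    if track.n_skipped:
        log.info("assign_footprints(%s): skipped %d alignments", sample_id,
                 track.n_skipped)
    return track


def load_bedgraph(path: PathLike, sample_id: str, strain: str = "custom",
                  replicate: int = 1, strand: str = ".") -> SampleTrack:
    """Load a per-nucleotide coverage track.

    Accepts 4-column bedGraph (seq_id, start, end, count; 0-based half-open)
    or 3-column TSV (seq_id, position, count; 0-based). Counts are stored
    with the given strand label ('.' = unstranded).
    """
    track = SampleTrack(sample_id=sample_id, strain=strain, replicate=replicate)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4:
                seq_id, start, end, value = fields[:4]
                for pos in range(int(start), int(end)):
                    track.add(seq_id, strand, pos, int(round(float(value))))
            else:
                seq_id, pos, value = fields[:3]
                track.add(seq_id, strand, int(pos), int(round(float(value))))
    return track


def write_bedgraph(track: SampleTrack, path: PathLike) -> None:
    """Write a SampleTrack as 4-column bedGraph (strand collapsed)."""
    merged: Dict[Tuple[str, int], int] = {}
    for (seq_id, _strand, pos), n in track.counts.items():
        merged[(seq_id, pos)] = merged.get((seq_id, pos), 0) + n
    with open(path, "w") as fh:
        for (seq_id, pos), n in sorted(merged.items()):
            fh.write(f"{seq_id}\t{pos}\t{pos + 1}\t{n}\n")


def codon_occupancy(track: SampleTrack, gene: GeneRecord) -> CodonOccupancy:
    """Sum nucleotide counts into consecutive codon bins along the coding strand."""
    n_codons = (gene.end - gene.start) // 3
    per_nt = np.zeros(gene.end - gene.start, dtype=float)
    counts = track.counts
    for strand in (gene.strand, "."):
        for i in range(gene.start, gene.end):
            n = counts.get((gene.seq_id, strand, i))
            if n:
                per_nt[i - gene.start] += n
    if gene.strand == "-":
        per_nt = per_nt[::-1]
    reads = per_nt.reshape(n_codons, 3).sum(axis=1)
    return CodonOccupancy(gene.gene_id, track.sample_id, reads)


def filter_covered(occ: CodonOccupancy,
                   threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> bool:
    """True iff the gene's mean reads/codon meets the coverage gate (inclusive)."""
    return occ.gene_mean >= threshold


def gene_totals(track: SampleTrack,
                genes: Iterable[GeneRecord]) -> Dict[str, float]:
    """Total footprints per gene (sum of the codon vector)."""
    return {g.gene_id: float(codon_occupancy(track, g).reads_per_codon.sum())
            for g in genes}


def replicate_correlation(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Pearson correlation of log10(total+1) footprints/gene between replicates."""
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    xa = np.log10(np.array([a[g] for g in shared]) + 1.0)
    xb = np.log10(np.array([b[g] for g in shared]) + 1.0)
    r, _ = stats.pearsonr(xa, xb)
    return float(r)


class ReplicateMean(NamedTuple):
    mean: float
    discordant: bool


def average_replicates(values: Iterable[float]) -> ReplicateMean:
    """Arithmetic mean across replicates, flagging >5-fold disagreement.

    A zero together with a positive value counts as discordant.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no replicate values")
    lo, hi = min(vals), max(vals)
    if hi <= 0:
        discordant = False
    elif lo <= 0:
        discordant = True
    else:
        discordant = (hi / lo) > REPLICATE_DISCORDANCE_FOLD
    return ReplicateMean(float(np.mean(vals)), discordant)
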