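"""Genome and annotation I/O.

Reads a reference genome (FASTA) and CDS annotation (GFF3 or tabular),
extracts strand-aware coding sequences, translates them with the bacterial
genetic code, and exposes :class:`GeneRecord` objects to all downstream
stages. Internal coordinates are 0-based half-open on the forward genomic
strand; file formats keep their native conventions (GFF3 is 1-based
inclusive).
"""

from __future__ import annotations

import logging
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: residues accepted in a genome sequence
DNA_ALPHABET = set("ACGTN")


class ReferenceError(ValueError):
    """Raised on malformed genome or annotation input."""


class InternalStopError(ReferenceError):
    """A CDS contains a stop codon before its final codon."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon index {codon_index}")


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by sequence id, in file order."""

    records: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneRecord:
    """One protein-coding gene.

    ``start``/``end`` are 0-based half-open genomic coordinates on the
    forward strand; ``cds_nt`` is the coding-strand nucleotide sequence
    (reverse complement of the genomic slice for minus-strand genes) and
    ``protein`` its translation with the terminal stop removed.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    cds_nt: str
    protein: str

    @property
    def n_codons(self) -> int:
        """Number of codons including the stop codon."""
        return len(self.cds_nt) // 3


def translate(cds_nt: str) -> str:
    """Translate a CDS with the bacterial genetic code (table 11).

    The terminal stop codon, when present, is dropped. An internal stop
    raises :class:`InternalStopError` carrying the offending 0-based codon
    index.
    """
    if len(cds_nt) % 3 != 0:
        raise ReferenceError(f"CDS length {len(cds_nt)} not divisible by 3")
    aa = str(Seq(cds_nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    pos = aa.find("*")
    if pos != -1:
        raise InternalStopError(pos)
    return aa


def load_genome(path: PathLike) -> GenomeSequence:
    """Load a FASTA genome, uppercasing residues and preserving order."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ReferenceError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ReferenceError(f"no sequences found in {path}")
    for seq_id, seq in records.items():
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ReferenceError(
                f"sequence {seq_id!r} contains non-DNA characters {sorted(bad)}"
            )
    return GenomeSequence(records)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(genome: GenomeSequence, seq_id: str, start: int, end: int,
                strand: str) -> str:
    """Coding-strand sequence for a 0-based half-open genomic interval."""
    segment = genome[seq_id][start:end]
    return reverse_complement(segment) if strand == "-" else segment


def _make_gene(gene_id: str, seq_id: str, start: int, end: int, strand: str,
               genome: GenomeSequence) -> Optional[GeneRecord]:
    """Build a GeneRecord, or return None (with a warning) if degenerate."""
    if seq_id not in genome:
        raise ReferenceError(f"annotation references unknown sequence {seq_id!r}")
    seqlen = len(genome[seq_id])
    if not (0 <= start < end <= seqlen):
        raise ReferenceError(
            f"gene {gene_id!r}: interval [{start},{end}) outside sequence "
            f"{seq_id!r} of length {seqlen}"
        )
    cds = extract_cds(genome, seq_id, start, end, strand)
    if len(cds) % 3 != 0:
        warnings.warn(f"gene {gene_id!r}: CDS length {len(cds)} not divisible "
                      "by 3; skipped")
        return None
    try:
        protein = translate(cds)
    except InternalStopError as exc:
        warnings.warn(f"gene {gene_id!r}: internal stop at codon "
                      f"{exc.codon_index}; skipped")
        return None
    return GeneRecord(gene_id, seq_id, start, end, strand, cds, protein)


def _dedup_longest(genes: Iterable[GeneRecord]) -> List[GeneRecord]:
    """Keep the longest CDS per gene_id (one ORF per gene)."""
    best: Dict[str, GeneRecord] = {}
    order: List[str] = []
    for g in genes:
        if g.gene_id not in best:
            best[g.gene_id] = g
            order.append(g.gene_id)
        elif len(g.cds_nt) > len(best[g.gene_id].cds_nt):
            best[g.gene_id] = g
    return [best[g] for g in order]


def _parse_gff3(path: PathLike, genome: GenomeSequence) -> List[GeneRecord]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(str(path), dbfn=tmp.name, force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
        genes = []
        for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
            gene_id = (feat.attributes.get("ID") or
                       feat.attributes.get("gene") or [feat.id])[0]
            rec = _make_gene(gene_id, feat.seqid, feat.start - 1, feat.end,
                             feat.strand, genome)
            if rec is not None:
                genes.append(rec)
    return genes


def _parse_tsv(path: PathLike, genome: GenomeSequence) -> List[GeneRecord]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header
                continue
            gene_id, seq_id, start, end, strand = fields[:5]
            rec = _make_gene(gene_id, seq_id, int(start) - 1, int(end),
                             strand, genome)
            if rec is not None:
                genes.append(rec)
    return genes


def load_annotation(path: PathLike, genome: GenomeSequence) -> List[GeneRecord]:
    """Load CDS features from GFF3 or 5-column TSV (both 1-based inclusive).

    Genes whose CDS length is not a multiple of 3 or that contain an internal
    stop codon are skipped with a warning; an unknown seq_id is fatal. When a
    gene_id occurs more than once, the longest CDS is kept.
    """
    path = Path(path)
    text_head = path.read_text()[:2048]
    if path.suffix.lower() in {".gff", ".gff3"} or text_head.startswith("##gff"):
        genes = _parse_gff3(path, genome)
    else:
        genes = _parse_tsv(path, genome)
    return _dedup_longest(genes)


def write_genome(genome: GenomeSequence, path: PathLike, width: int = 70) -> None:
    """Write a GenomeSequence as FASTA."""
    with open(path, "w") as fh:
        for seq_id, seq in genome.records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotation_gff3(genes: Iterable[GeneRecord], path: PathLike) -> None:
    """Write GeneRecords as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join([
                g.seq_id, "ribopause", "CDS", str(g.start + 1), str(g.end),
                ".", g.strand, "0", attrs,
            ]) + "\n")
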