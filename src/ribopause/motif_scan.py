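"""Diprolyl (PPX) motif enumeration and local sequence context.

A PPX site is any pair of consecutive prolines followed by a residue X; X
occupies the ribosomal A site while the second proline sits in the P site.
A run of L prolines followed by X therefore yields L-1 sites (e.g. IPPPE
emits PPP and PPE, shifted by one), matching the double-listing convention
for triprolyl motifs. Context fields record the residues two (Z-2) and three
(Z-3) positions upstream of the P-site proline and the 20 residues upstream
of the motif, '-'-padded at the protein start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: physicochemical classes used for A-site / upstream residue analysis
RESIDUE_CLASSES = {
    "acidic": set("DE"),
    "basic": set("KRH"),
    "amide": set("NQ"),
    "hydroxy": set("STY"),
    "proline": set("P"),
    "glycine": set("G"),
    "hydrophobic_aromatic": set("AVLIMFWC"),
}

_CLASS_OF = {aa: name for name, members in RESIDUE_CLASSES.items()
             for aa in members}


def classify_residue(aa: str) -> str:
    """Physicochemical class of a residue ('-' padding maps to 'none')."""
    if aa == "-":
        return "none"
    cls = _CLASS_OF.get(aa)
    if cls is None:
        warnings.warn(f"unclassified residue {aa!r}")
        return "other"
    return cls


@dataclass
class MotifSite:
    """One PPX occurrence in a protein.

    ``x_codon_index`` is the 1-based codon index of X; ``window`` holds the
    1-based codon indices of (P-1, P_P, X_A). ``z2``/``z3`` are the residues
    two and three positions upstream of the P-site proline ('-' when the
    motif starts at or near the protein N terminus).
    """

    gene_id: str
    motif: str
    x_codon_index: int
    window: Tuple[int, int, int]
    z2: str = "-"
    z3: str = "-"
    upstream20: str = "-" * 20

    @property
    def x(self) -> str:
        return self.motif[2]


def find_ppx_sites(protein: str, gene_id: str = "") -> List[MotifSite]:
    """Enumerate every PPX site in a protein, in ascending position order.

    A site is emitted for each 0-based index i with protein[i] == 'P',
    protein[i+1] == 'P' and an existing A-site residue protein[i+2]; a
    proline run that ends the protein (no X) emits nothing, and the stop
    codon is never X.
    """
    if not protein:
        raise ValueError("empty protein")
    sites = []
    for i in range(len(protein) - 2):
        if protein[i] == "P" and protein[i + 1] == "P":
            motif = protein[i:i + 3]
            site = MotifSite(
                gene_id=gene_id,
                motif=motif,
                x_codon_index=i + 3,
                window=(i + 1, i + 2, i + 3),
            )
            sites.append(extract_context(protein, site))
    return sites


def extract_context(protein: str, site: MotifSite) -> MotifSite:
    """Fill z2/z3 and the 20-residue upstream string for a site.

    ``upstream20`` is the 20 residues immediately preceding the first
    proline of the motif, left-padded with '-' when the motif lies within
    20 residues of the protein start.
    """
    i = site.window[0] - 1  # 0-based index of P-1
    site.z2 = protein[i - 1] if i >= 1 else "-"
    site.z3 = protein[i - 2] if i >= 2 else "-"
    upstream = protein[max(0, i - 20):i]
    site.upstream20 = "-" * (20 - len(upstream)) + upstream
    return site


def scan_genes(genes) -> List[MotifSite]:
    """All PPX sites over a collection of GeneRecords, sorted by
    (gene_id, x_codon_index)."""
    sites: List[MotifSite] = []
    for g in genes:
        sites.extend(find_ppx_sites(g.protein, gene_id=g.gene_id))
    sites.sort(key=lambda s: (s.gene_id, s.x_codon_index))
    return sites


def sites_to_tsv(sites: Iterable[MotifSite], path) -> None:
    """Write sites as TSV (fixed column order)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmotif\tx_codon_index\tz3\tz2\tupstream20\n")
        for s in sites:
            fh.write(f"{s.gene_id}\t{s.motif}\t{s.x_codon_index}\t"
                     f"{s.z3}\t{s.z2}\t{s.upstream20}\n")
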