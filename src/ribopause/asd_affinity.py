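"""Anti-Shine-Dalgarno hybridization scan.

Scores the affinity between short mRNA windows upstream of a stall motif and
the 16S rRNA anti-Shine-Dalgarno (aSD) 8-mer 5'-CACCUCCU-3' with a
duplex-only nearest-neighbor model: the minimum, over all contiguous
antiparallel registers of >= 2 consecutive base pairs (Watson-Crick or GU
wobble), of the summed stack free energies at 37 C. Intramolecular folding,
bulges and internal loops are deliberately out of model — the aSD is only 8
nt and the scan is a short hybridization screen. Offsets are measured from
the third nucleotide of the A-site (X) codon (offset 0), negative values
pointing upstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .motif_scan import MotifSite

PathLike = Union[str, Path]

ASD_SEQUENCE = "CACCUCCU"

#: best duplex at or below this level counts as an aSD weak binder
WEAK_BINDER_CUTOFF = -2.0
#: best duplex at or below this level counts as SD-like
SD_LIKE_CUTOFF = -4.0

#: offsets scanned by default (3' end of the window relative to the
#: third nucleotide of the X codon)
DEFAULT_OFFSETS = range(-20, -4)

#: band reported in the summary: 7-9 nt upstream of the X codon third base
SUMMARY_BAND = (-9, -7)

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
          ("G", "U"), ("U", "G")}


def _load_stack_table(path: Optional[PathLike] = None) -> Dict[str, float]:
    if path is None:
        ref = importlib.resources.files("ribopause.data") / "rna_stack_params.tsv"
        with importlib.resources.as_file(ref) as p:
            return _load_stack_table(p)
    table: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("top_bottom"):
                continue
            key, dg = line.split("\t")[:2]
            table[key] = float(dg)
            top, bottom = key.split("/")
            # symmetric orientation: rotate the stack 180 degrees
            table.setdefault(bottom[::-1] + "/" + top[::-1], float(dg))
    return table


_STACKS: Optional[Dict[str, float]] = None


def stack_table() -> Dict[str, float]:
    """The packaged nearest-neighbor stack table (lazy singleton)."""
    global _STACKS
    if _STACKS is None:
        _STACKS = _load_stack_table()
    return _STACKS


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)}")
    return seq


def is_pair(a: str, b: str) -> bool:
    """Watson-Crick or GU wobble pair."""
    return (a, b) in _PAIRS


@dataclass
class DuplexResult:
    """Best duplex between one window and the aSD.

    ``pairing`` lists (window index, asd index) pairs of the optimal duplex;
    ``delta_g`` is its summed stack free energy in kcal/mol, reported as 0
    with empty pairing when no favorable duplex exists. ``offset`` is filled
    by the positional scan.
    """

    window: str
    delta_g: float
    pairing: List[Tuple[int, int]] = field(default_factory=list)
    offset: Optional[int] = None
    truncated: bool = False


def duplex_energy(window: str, asd: str = ASD_SEQUENCE,
                  stacks: Optional[Dict[str, float]] = None) -> DuplexResult:
    """Minimum free energy of a contiguous duplex between window and aSD.

    Considers every antiparallel register of the two strands and every
    contiguous run of >= 2 consecutive base pairs within it, summing
    nearest-neighbor stack energies; the global minimum is returned. A
    positive optimum is reported as 0 kcal/mol with no pairing.
    """
    window = _to_rna(window)
    asd = _to_rna(asd)
    if not (2 <= len(window) <= 24):
        raise ValueError(f"window length {len(window)} out of range")
    stacks = stacks or stack_table()

    best_dg = 0.0
    best_pairing: List[Tuple[int, int]] = []
    nw, na = len(window), len(asd)
    # Antiparallel alignment: window position i pairs aSD position j with
    # i + j == s for some register sum s.
    for s in range(1, nw + na - 2):
        # collect pair mask along the register
        positions = [(i, s - i) for i in range(max(0, s - na + 1),
                                               min(nw, s + 1))
                     if 0 <= s - i < na]
        paired = [is_pair(window[i], asd[j]) for i, j in positions]
        # maximal runs of consecutive pairs
        k = 0
        while k < len(positions):
            if not paired[k]:
                k += 1
                continue
            run_start = k
            while k + 1 < len(positions) and paired[k + 1]:
                k += 1
            run = positions[run_start:k + 1]
            k += 1
            if len(run) < 2:
                continue
            # stack energies between adjacent pairs of the run
            energies = []
            for (i1, j1), (i2, j2) in zip(run, run[1:]):
                key = window[i1] + window[i2] + "/" + asd[j1] + asd[j2]
                energies.append(stacks[key])
            # best contiguous sub-duplex = minimum-sum subarray (>=1 stack)
            cur = 0.0
            cur_start = 0
            for e_idx, e in enumerate(energies):
                if cur > 0:
                    cur = 0.0
                    cur_start = e_idx
                cur += e
                if cur < best_dg:
                    best_dg = cur
                    best_pairing = run[cur_start:e_idx + 2]
    if best_dg >= 0:
        return DuplexResult(window=window, delta_g=0.0, pairing=[])
    return DuplexResult(window=window, delta_g=best_dg, pairing=best_pairing)


@dataclass
class AffinityScan:
    """Positional aSD affinity profile upstream of one motif site."""

    gene_id: str
    results: List[DuplexResult]
    best_in_band: float
    weak_binder: bool
    sd_like: bool
    truncated: bool


def scan_upstream_affinity(cds_nt: str, site: MotifSite,
                           offsets: Sequence[int] = DEFAULT_OFFSETS,
                           window_length: int = len(ASD_SEQUENCE),
                           asd: str = ASD_SEQUENCE,
                           band: Tuple[int, int] = SUMMARY_BAND) -> AffinityScan:
    """Scan aSD duplex energy at each offset upstream of a site.

    Offset o places the 3' end of the window o nucleotides from the third
    nucleotide of the X codon (offset 0 = that nucleotide itself). Windows
    that would extend upstream of the CDS start are truncated (>= 6 nt) or
    skipped, and the scan is flagged.
    """
    anchor = 3 * (site.x_codon_index - 1) + 2  # CDS index of X codon 3rd nt
    if anchor >= len(cds_nt):
        raise IndexError(f"site X codon {site.x_codon_index} outside CDS")
    results: List[DuplexResult] = []
    truncated_any = False
    for o in offsets:
        end = anchor + o + 1  # exclusive
        start = end - window_length
        truncated = False
        if end <= 0:
            truncated_any = True
            continue
        if start < 0:
            start = 0
            truncated = True
            truncated_any = True
            if end - start < 6:
                continue
        res = duplex_energy(cds_nt[start:end], asd)
        res.offset = o
        res.truncated = truncated
        results.append(res)
    in_band = [r.delta_g for r in results
               if band[0] <= (r.offset or 0) <= band[1]]
    best = min(in_band) if in_band else 0.0
    return AffinityScan(
        gene_id=site.gene_id,
        results=results,
        best_in_band=best,
        weak_binder=best <= WEAK_BINDER_CUTOFF,
        sd_like=best <= SD_LIKE_CUTOFF,
        truncated=truncated_any,
    )
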