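"""Pausing-index computation, classification and strain comparison.

The pausing index of a site is the mean ribosome footprint density over its
3-codon window (P-1, P_P, X_A) divided by the mean density of the whole ORF.
An index >= 10 marks a strong pause, > 2 an elevated one, and <= 1 a
non-pausing site. A site is called EF-P dependent when it is strong in the
efp-deletion strain and its index rose at least ``fold_threshold``-fold over
wild type. The de-novo scan finds pause windows from occupancy alone
(normalized occupancy >= threshold, consecutive codons merged), which also
captures pauses with no PPX motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import MotifSite
from .occupancy import CodonOccupancy, average_replicates

STRONG_THRESHOLD = 10.0
ELEVATED_THRESHOLD = 2.0
NONPAUSING_THRESHOLD = 1.0
FOLD_THRESHOLD = 3.0
PSEUDOCOUNT = 0.1

WT = "WT"
DELTA_EFP = "delta_efp"
COMPLEMENTED = "complemented"


def pausing_index(occ: CodonOccupancy, window: Sequence[int],
                  window_mode: str = "mean") -> float:
    """Ratio of window footprint density to whole-gene density.

    ``window`` holds 1-based codon indices. ``window_mode`` selects the
    window statistic: 'mean' (default) or 'max'. Raises on an uncovered
    gene (gene_mean == 0); callers drop such sites.
    """
    mean = occ.gene_mean
    if mean == 0:
        raise ZeroDivisionError(f"gene {occ.gene_id}: zero mean coverage")
    idx = np.asarray(window, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= len(occ.reads_per_codon):
        raise IndexError(f"window {list(window)} outside gene {occ.gene_id}")
    vals = occ.reads_per_codon[idx]
    stat = float(np.max(vals)) if window_mode == "max" else float(np.mean(vals))
    return stat / mean


def classify_pause(index: float,
                   strong: float = STRONG_THRESHOLD,
                   elevated: float = ELEVATED_THRESHOLD,
                   nonpausing: float = NONPAUSING_THRESHOLD) -> str:
    """Threshold classification: strong >= 10, elevated > 2, non_pausing <= 1."""
    if index < 0:
        raise ValueError(f"negative pausing index {index}")
    if index >= strong:
        return "strong"
    if index > elevated:
        return "elevated"
    if index <= nonpausing:
        return "non_pausing"
    return "neutral"


@dataclass
class PauseCall:
    """Replicate-averaged pausing indices for one site across strains."""

    site: MotifSite
    index_by_strain: Dict[str, float]
    classification: Dict[str, str]
    fold_change: Optional[float] = None
    efp_dependent: bool = False
    complement_restored: Optional[bool] = None
    wt_near_zero: bool = False
    replicates_discordant: bool = False


def compare_strains(site: MotifSite,
                    indices: Mapping[str, Sequence[float]],
                    pseudocount: float = PSEUDOCOUNT,
                    fold_threshold: float = FOLD_THRESHOLD,
                    strong_threshold: float = STRONG_THRESHOLD) -> PauseCall:
    """Aggregate per-replicate indices into a strain comparison.

    ``indices`` maps strain name to per-replicate pausing indices. The
    fold change is delta_efp / WT; when the WT index falls below the
    pseudocount, the pseudocount is added to both and the call is flagged
    ``wt_near_zero`` (the raw values are preserved in ``index_by_strain``).
    """
    averaged: Dict[str, float] = {}
    discordant = False
    for strain, vals in indices.items():
        rep = average_replicates(vals)
        averaged[strain] = rep.mean
        discordant = discordant or rep.discordant
    classification = {s: classify_pause(v) for s, v in averaged.items()}

    call = PauseCall(site=site, index_by_strain=averaged,
                     classification=classification,
                     replicates_discordant=discordant)
    wt = averaged.get(WT)
    defp = averaged.get(DELTA_EFP)
    if wt is not None and defp is not None:
        if wt < pseudocount:
            call.fold_change = (defp + pseudocount) / (wt + pseudocount)
            call.wt_near_zero = True
        else:
            call.fold_change = defp / wt
        call.efp_dependent = (defp >= strong_threshold
                              and call.fold_change >= fold_threshold)
    comp = averaged.get(COMPLEMENTED)
    if comp is not None and defp is not None:
        call.complement_restored = comp < defp
    return call


@dataclass
class PauseWindow:
    """A de-novo pause: maximal run of codons above the occupancy threshold."""

    gene_id: str
    start_codon: int  # 1-based, inclusive
    end_codon: int    # 1-based, inclusive
    peak_codon: int
    peak_value: float
    overlaps_ppx: bool = False


def scan_denovo_pauses(occ: CodonOccupancy, threshold: float = STRONG_THRESHOLD,
                       ppx_sites: Iterable[MotifSite] = ()) -> List[PauseWindow]:
    """Motif-agnostic pause scan on normalized occupancy.

    Maximal runs of consecutive codons with normalized occupancy >= threshold
    are merged into single windows; windows overlapping a PPX 3-codon window
    are cross-annotated, the remainder are non-PPX pauses.
    """
    norm = occ.normalized()
    above = norm >= threshold
    windows: List[PauseWindow] = []
    i = 0
    n = len(norm)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            peak = i + int(np.argmax(norm[i:j + 1]))
            windows.append(PauseWindow(
                gene_id=occ.gene_id, start_codon=i + 1, end_codon=j + 1,
                peak_codon=peak + 1, peak_value=float(norm[peak])))
            i = j + 1
        else:
            i += 1
    spans = [(s.window[0], s.window[-1]) for s in ppx_sites
             if s.gene_id == occ.gene_id]
    for w in windows:
        w.overlaps_ppx = any(w.start_codon <= hi and w.end_codon >= lo
                             for lo, hi in spans)
    return windows


def build_pause_table(calls: Iterable[PauseCall],
                      protein_ratios: Optional[Mapping[str, float]] = None
                      ) -> pd.DataFrame:
    """One row per site, sorted by descending efp-deletion index.

    Columns mirror a strain-comparison report: gene, motif, 20-residue
    upstream context, per-strain indices, fold change, classification and
    EF-P dependence; an optional join column carries external protein
    abundance ratios.
    """
    rows = []
    for c in calls:
        row = {
            "gene_id": c.site.gene_id,
            "motif": c.site.motif,
            "x_codon_index": c.site.x_codon_index,
            "z3": c.site.z3,
            "z2": c.site.z2,
            "upstream20": c.site.upstream20,
            "index_wt": c.index_by_strain.get(WT, np.nan),
            "index_delta_efp": c.index_by_strain.get(DELTA_EFP, np.nan),
            "index_complemented": c.index_by_strain.get(COMPLEMENTED, np.nan),
            "fold_change": np.nan if c.fold_change is None else c.fold_change,
            "classification_delta_efp": c.classification.get(DELTA_EFP, "n/a"),
            "efp_dependent": c.efp_dependent,
            "wt_near_zero": c.wt_near_zero,
        }
        if protein_ratios is not None:
            row["protein_ratio"] = protein_ratios.get(c.site.gene_id, np.nan)
        rows.append(row)
    columns = ["gene_id", "motif", "x_codon_index", "z3", "z2", "upstream20",
               "index_wt", "index_delta_efp", "index_complemented",
               "fold_change", "classification_delta_efp", "efp_dependent",
               "wt_near_zero"]
    if protein_ratios is not None:
        columns.append("protein_ratio")
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values("index_delta_efp", ascending=False,
                                  kind="mergesort").reset_index(drop=True)
    return table
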