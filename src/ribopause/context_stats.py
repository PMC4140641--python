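"""Aggregate context analyses over pause calls.

Covers the Z-2 x A-site (ZPPX) matrix, amino-acid-class contingency
summaries of pausing vs non-pausing sites, pausing-index histograms, A-site
codon rarity annotation, and concordance between ribosome-footprint ratios
and external protein-abundance ratios. All ratio comparisons use the
efp-deletion / wild-type orientation internally.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .motif_scan import classify_residue
from .pause_call import DELTA_EFP, NONPAUSING_THRESHOLD, STRONG_THRESHOLD, PauseCall

PathLike = Union[str, Path]

DEFAULT_HISTOGRAM_EDGES = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, np.inf)

CONCORDANCE_LABELS = ("both_0.5-2", "ribo_up_only", "both_up",
                      "ribo_down_only", "both_down", "discordant")


def zppx_matrix(calls: Iterable[PauseCall]) -> pd.DataFrame:
    """Aggregate efp-deletion indices by (Z-2 residue, A-site residue).

    One row per observed (z, x) combination; combinations with no sites are
    absent, not zero. ``n_strong``/``n_nonpausing`` count sites at the
    strong (>=10) and non-pausing (<=1) thresholds in the deletion strain.
    """
    rows: Dict[Tuple[str, str], Dict[str, float]] = {}
    for c in calls:
        idx = c.index_by_strain.get(DELTA_EFP)
        if idx is None:
            continue
        key = (c.site.z2, c.site.x)
        cell = rows.setdefault(key, {"n_sites": 0, "sum_index": 0.0,
                                     "n_strong": 0, "n_nonpausing": 0})
        cell["n_sites"] += 1
        cell["sum_index"] += idx
        if idx >= STRONG_THRESHOLD:
            cell["n_strong"] += 1
        if idx <= NONPAUSING_THRESHOLD:
            cell["n_nonpausing"] += 1
    records = [{"z": z, "x": x,
                "n_sites": int(cell["n_sites"]),
                "mean_index_delta_efp": cell["sum_index"] / cell["n_sites"],
                "n_strong": int(cell["n_strong"]),
                "n_nonpausing": int(cell["n_nonpausing"])}
               for (z, x), cell in sorted(rows.items())]
    return pd.DataFrame(records,
                        columns=["z", "x", "n_sites", "mean_index_delta_efp",
                                 "n_strong", "n_nonpausing"])


def class_summary(calls: Iterable[PauseCall]) -> pd.DataFrame:
    """Contingency of (Z-2 class, X class) over pausing vs non-pausing sites.

    A site counts as pausing when its efp-deletion index is strong (>=10)
    and as non-pausing when it is <=1; intermediate sites are excluded, so
    the table contrasts the two well-defined sets.
    """
    rows: Dict[Tuple[str, str], Dict[str, int]] = {}
    for c in calls:
        idx = c.index_by_strain.get(DELTA_EFP)
        if idx is None:
            continue
        key = (classify_residue(c.site.z2), classify_residue(c.site.x))
        cell = rows.setdefault(key, {"n_pausing": 0, "n_nonpausing": 0})
        if idx >= STRONG_THRESHOLD:
            cell["n_pausing"] += 1
        elif idx <= NONPAUSING_THRESHOLD:
            cell["n_nonpausing"] += 1
    records = []
    for (zc, xc), cell in sorted(rows.items()):
        if cell["n_pausing"] == 0 and cell["n_nonpausing"] == 0:
            continue
        records.append({"z2_class": zc, "x_class": xc,
                        "n_pausing": cell["n_pausing"],
                        "n_nonpausing": cell["n_nonpausing"],
                        "pausing_only": cell["n_nonpausing"] == 0})
    return pd.DataFrame(records, columns=["z2_class", "x_class", "n_pausing",
                                          "n_nonpausing", "pausing_only"])


def pausing_histogram(indices: Sequence[float],
                      edges: Sequence[float] = DEFAULT_HISTOGRAM_EDGES
                      ) -> pd.DataFrame:
    """Bin pausing indices into left-inclusive, right-exclusive bins."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("histogram edges must be strictly increasing")
    vals = np.asarray(list(indices), dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram closes the final bin on the right; with an inf edge the
    # convention is left-inclusive everywhere.
    total = counts.sum()
    frac = counts / total if total else np.zeros_like(counts, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    return pd.DataFrame({"bin": labels, "count": counts, "fraction": frac})


class CodonUsageTable:
    """Per-thousand codon usage with a rarity cutoff (bottom quartile)."""

    def __init__(self, frequencies: Mapping[str, float],
                 amino_acids: Mapping[str, str],
                 rare_quantile: float = 0.25):
        self.frequencies = dict(frequencies)
        self.amino_acids = dict(amino_acids)
        sense = [f for c, f in self.frequencies.items()
                 if self.amino_acids.get(c) != "*"]
        self.rare_cutoff = float(np.quantile(sense, rare_quantile))

    @classmethod
    def from_tsv(cls, path: PathLike, rare_quantile: float = 0.25
                 ) -> "CodonUsageTable":
        freqs: Dict[str, float] = {}
        aas: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("codon"):
                    continue
                codon, aa, per_thousand = line.split("\t")
                codon = codon.upper().replace("U", "T")
                freqs[codon] = float(per_thousand)
                aas[codon] = aa
        return cls(freqs, aas, rare_quantile)

    @classmethod
    def default(cls) -> "CodonUsageTable":
        ref = importlib.resources.files("ribopause.data") / "codon_usage_ecoli.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def codon_rarity(codon: str, usage: Optional[CodonUsageTable] = None,
                 cutoff: Optional[float] = None) -> Dict[str, object]:
    """Frequency (per thousand) and rarity flag for a sense codon.

    Rarity means frequency below the cutoff (default: the table's bottom
    quartile over sense codons). Stop or unknown codons raise.
    """
    usage = usage or CodonUsageTable.default()
    codon = codon.upper().replace("U", "T")
    if codon not in usage.frequencies:
        raise ValueError(f"unknown codon {codon!r}")
    if usage.amino_acids.get(codon) == "*":
        raise ValueError(f"stop codon {codon!r} has no A-site tRNA")
    freq = usage.frequencies[codon]
    threshold = usage.rare_cutoff if cutoff is None else cutoff
    return {"frequency": freq, "rare": freq < threshold}


def concordance(ribo_ratio: Mapping[str, float],
                protein_ratio: Mapping[str, float],
                protein_orientation: str = "wt_over_delta") -> pd.DataFrame:
    """Joint binning of footprint and protein-abundance fold changes.

    ``ribo_ratio`` is delta_efp/WT footprints per gene. ``protein_ratio``
    defaults to the WT/delta_efp orientation of SILAC-style tables and is
    inverted internally so both axes compare delta_efp/WT. Each shared gene
    falls in exactly one bin of the 0.5-2 / >2 / <0.5 partition on both
    axes; a change on one axis unmatched by the other is 'discordant'
    unless it is a footprint-only change, which gets its own bin.
    """
    shared = sorted(set(ribo_ratio) & set(protein_ratio))
    if not shared:
        raise ValueError("no shared genes between ratio tables")

    def _level(x: float) -> str:
        if x > 2.0:
            return "up"
        if x < 0.5:
            return "down"
        return "mid"

    counts = {label: 0 for label in CONCORDANCE_LABELS}
    for g in shared:
        r = ribo_ratio[g]
        p = protein_ratio[g]
        if protein_orientation == "wt_over_delta":
            p = 1.0 / p if p != 0 else np.inf
        rl, pl = _level(r), _level(p)
        if rl == "mid" and pl == "mid":
            label = "both_0.5-2"
        elif rl == "up" and pl == "up":
            label = "both_up"
        elif rl == "down" and pl == "down":
            label = "both_down"
        elif rl == "up" and pl == "mid":
            label = "ribo_up_only"
        elif rl == "down" and pl == "mid":
            label = "ribo_down_only"
        else:
            label = "discordant"
        counts[label] += 1
    n = len(shared)
    return pd.DataFrame({
        "label": list(CONCORDANCE_LABELS),
        "count": [counts[k] for k in CONCORDANCE_LABELS],
        "fraction": [counts[k] / n for k in CONCORDANCE_LABELS],
    })
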