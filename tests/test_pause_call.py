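"""Pausing index, classification, strain comparison and de-novo scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopause.motif_scan import MotifSite, find_ppx_sites
from ribopause.occupancy import CodonOccupancy
from ribopause.pause_call import (build_pause_table, classify_pause,
                                  compare_strains, pausing_index,
                                  scan_denovo_pauses)


def _occ(values):
    return CodonOccupancy("g", "s", np.asarray(values, dtype=float))


def _site(gene_id="g", motif="PPK", x=6, z2="E", z3="P"):
    return MotifSite(gene_id=gene_id, motif=motif, x_codon_index=x,
                     window=(x - 2, x - 1, x), z2=z2, z3=z3)


class TestPausingIndex:
    def test_uniform_occupancy_gives_one(self):
        assert pausing_index(_occ([4] * 10), (3, 4, 5)) == pytest.approx(1.0)

    def test_single_codon_window(self):
        occ = _occ([1, 1, 1, 1, 50, 1, 1, 1, 1, 1])
        assert pausing_index(occ, (5,)) == pytest.approx(50 / 5.9)

    def test_three_codon_window(self):
        occ = _occ([1, 1, 1, 1, 50, 1, 1, 1, 1, 1])
        assert pausing_index(occ, (4, 5, 6)) == pytest.approx(52 / 3 / 5.9)

    def test_window_max_mode(self):
        occ = _occ([1, 1, 1, 1, 50, 1, 1, 1, 1, 1])
        assert pausing_index(occ, (4, 5, 6), "max") == pytest.approx(50 / 5.9)

    def test_zero_mean_raises(self):
        with pytest.raises(ZeroDivisionError):
            pausing_index(_occ([0, 0, 0]), (1,))

    def test_exhaustive_single_codon_scan_averages_to_one(self):
        rng = np.random.default_rng(3)
        occ = _occ(rng.poisson(8, 120) + 1)
        indices = [pausing_index(occ, (c,)) for c in range(1, 121)]
        assert np.mean(indices) == pytest.approx(1.0)


class TestClassification:
    @pytest.mark.parametrize("index,label", [
        (15.77, "strong"),    # sgrR-scale deletion-strain index
        (10.0, "strong"),     # inclusive boundary
        (2.5, "elevated"),
        (2.0, "neutral"),
        (1.5, "neutral"),
        (1.0, "non_pausing"),
        (0.9, "non_pausing"),
        (0.0, "non_pausing"),
    ])
    def test_thresholds(self, index, label):
        assert classify_pause(index) == label

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            classify_pause(-0.1)

    def test_monotone_in_index(self):
        order = {"non_pausing": 0, "neutral": 1, "elevated": 2, "strong": 3}
        grid = np.linspace(0, 20, 401)
        ranks = [order[classify_pause(x)] for x in grid]
        assert ranks == sorted(ranks)


class TestCompareStrains:
    def test_efp_dependent_site(self):
        # ubiD-like: WT ~1, deletion strain ~14 -> dependent
        call = compare_strains(_site(), {"WT": [1.0, 1.1],
                                         "delta_efp": [13.5, 14.26]})
        assert call.index_by_strain["WT"] == pytest.approx(1.05)
        assert call.fold_change == pytest.approx(13.88 / 1.05)
        assert call.efp_dependent
        assert not call.wt_near_zero

    def test_zero_wt_uses_pseudocount(self):
        # fliP-like: undetectable in WT
        call = compare_strains(_site(), {"WT": [0.0, 0.0],
                                         "delta_efp": [16.65, 16.65]})
        assert call.wt_near_zero
        assert call.fold_change == pytest.approx(16.75 / 0.1)
        assert call.efp_dependent

    def test_wt_strong_site_not_efp_dependent(self):
        # sgrR-like: strong in both strains, fold below 3
        call = compare_strains(_site(), {"WT": [10.75], "delta_efp": [15.77]})
        assert call.classification["delta_efp"] == "strong"
        assert not call.efp_dependent

    def test_missing_strain_gives_partial_call(self):
        call = compare_strains(_site(), {"delta_efp": [12.0]})
        assert call.fold_change is None
        assert not call.efp_dependent

    def test_complement_restoration_flag(self):
        call = compare_strains(_site(), {"WT": [1.0], "delta_efp": [12.0],
                                         "complemented": [5.0]})
        assert call.complement_restored is True


class TestDenovoScan:
    def test_single_codon_peak(self):
        vec = np.ones(50)
        vec[10] = 600.0  # normalized value 12.9
        occ = _occ(vec)
        (w,) = scan_denovo_pauses(occ)
        assert w.peak_codon == 11
        assert w.peak_value == pytest.approx(occ.normalized()[10])

    def test_subthreshold_peak_ignored(self):
        vec = np.ones(100)
        vec[5] = vec.sum() * 9.9 / (100 + vec[5] - 1)  # normalized < 10
        assert scan_denovo_pauses(_occ(vec)) == []

    def test_adjacent_peaks_merge(self):
        vec = np.ones(100)
        vec[6] = vec[7] = 500.0
        (w,) = scan_denovo_pauses(_occ(vec))
        assert (w.start_codon, w.end_codon) == (7, 8)

    def test_ppx_overlap_annotation(self):
        vec = np.ones(50)
        vec[10] = 600.0
        site = MotifSite("g", "PPK", 11, window=(9, 10, 11))
        (w,) = scan_denovo_pauses(_occ(vec), ppx_sites=[site])
        assert w.overlaps_ppx

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 30), min_size=3, max_size=60))
    def test_matches_per_codon_oracle(self, values):
        vec = np.asarray(values)
        if vec.sum() == 0:
            return
        occ = _occ(vec)
        norm = occ.normalized()
        flagged = {c for w in scan_denovo_pauses(occ)
                   for c in range(w.start_codon, w.end_codon + 1)}
        expected = {c + 1 for c in range(len(norm)) if norm[c] >= 10.0}
        assert flagged == expected


class TestPauseTable:
    def test_empty_calls_give_header_only(self):
        table = build_pause_table([])
        assert len(table) == 0
        assert "index_delta_efp" in table.columns

    def test_sorted_by_deletion_index_descending(self):
        calls = [compare_strains(_site(gene_id=f"g{i}"),
                                 {"WT": [1.0], "delta_efp": [float(v)]})
                 for i, v in enumerate([5, 20, 12])]
        table = build_pause_table(calls)
        assert list(table["index_delta_efp"]) == [20.0, 12.0, 5.0]

    def test_triproline_gene_yields_offset_upstream_rows(self):
        protein = "M" + "ACDEFGHIKLMNQRSTVWYA" + "PPPE" + "AAAAA"
        sites = find_ppx_sites(protein)
        ppp, ppe = [s for s in sites if s.motif in ("PPP", "PPE")]
        calls = [compare_strains(s, {"WT": [1.0], "delta_efp": [13.0]})
                 for s in (ppp, ppe)]
        table = build_pause_table(calls)
        u1, u2 = table["upstream20"]
        assert u1[1:] == u2[:-1]  # offset by one residue

    def test_protein_ratio_join_column(self):
        call = compare_strains(_site(gene_id="gX"),
                               {"WT": [1.0], "delta_efp": [12.0]})
        table = build_pause_table([call], protein_ratios={"gX": 2.5})
        assert table["protein_ratio"].iloc[0] == 2.5
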