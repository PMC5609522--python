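"""Candidate screen and protein properties: motif scan, TM prediction,
molecular weight, isoelectric point, full-proteome screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetaqp import synthetic_data as sd
from beetaqp.sequence_screen import (NPA_THIRD_RESIDUES, ScreenConfig,
                                     compute_mw, compute_pi, net_charge,
                                     predict_tm_segments, scan_npa_motifs,
                                     screen_proteome)
from beetaqp._residues import AMINO_ACIDS

AA = list(AMINO_ACIDS)
seqs = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)


def oracle_npa_scan(seq):
    """Window-by-window scan honouring non-overlap, for cross-checking."""
    hits, i = [], 0
    while i <= len(seq) - 3:
        w = seq[i:i + 3]
        if w[0] == "N" and w[1] == "P" and w[2] in NPA_THIRD_RESIDUES:
            hits.append((i, w))
            i += 3
        else:
            i += 1
    return hits


class TestNpaScan:
    def test_planted_motif(self):
        hits = scan_npa_motifs("AAAANPAAAA")
        assert [(h.position, h.triplet) for h in hits] == [(4, "NPA")]

    def test_nip5_type_lb_le_pair(self):
        seq = "M" + "NPS" + "A" * 96 + "NPV" + "A" * 20
        hits = scan_npa_motifs(seq)
        assert [(h.position, h.triplet) for h in hits] == [(1, "NPS"), (100, "NPV")]

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            scan_npa_motifs("NPAX1")

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            seq = "".join(rng.choice(AA, size=300))
            got = [(h.position, h.triplet) for h in scan_npa_motifs(seq)]
            assert got == oracle_npa_scan(seq)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=seqs, suffix=st.text(alphabet="DEKR", max_size=30))
    def test_invariant_to_nonmatching_suffix(self, seq, suffix):
        before = [(h.position, h.triplet) for h in scan_npa_motifs(seq)]
        # a suffix of charged residues cannot complete an NPA-like motif
        # except across the boundary; drop boundary-crossing hits
        after = [(h.position, h.triplet)
                 for h in scan_npa_motifs(seq + suffix)
                 if h.position + 3 <= len(seq)]
        assert after[:len(before)] == before


class TestTmPrediction:
    def test_single_hydrophobic_block(self):
        seq = "D" * 30 + "I" * 30 + "D" * 30
        segs = predict_tm_segments(seq)
        assert len(segs) == 1
        s, e = segs[0]
        assert s >= 20 and e <= 70  # inside/around the I block

    def test_hydrophilic_sequence_has_no_segment(self):
        assert predict_tm_segments("D" * 80) == []

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            predict_tm_segments("A" * 50, window=10)

    def test_recovers_six_planted_tm_blocks(self):
        seq = sd.subgroup_scaffold("PIP2")
        segs = predict_tm_segments(seq)
        assert len(segs) == 6
        for planted, predicted in zip(sd.TM_INTERVALS, segs):
            ps, pe = planted
            s, e = predicted
            assert max(s, ps) < min(e, pe)  # overlap

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=19, max_size=200))
    def test_segments_sorted_nonoverlapping(self, seq):
        segs = predict_tm_segments(seq)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert e1 < s2
        assert sum(e - s for s, e in segs) <= len(seq)


class TestMolecularWeight:
    def test_glycine(self):
        assert compute_mw("G") * 1000 == pytest.approx(75.07, abs=0.01)

    def test_diglycine_loses_one_water(self):
        assert compute_mw("GG") * 1000 == pytest.approx(132.12, abs=0.01)

    def test_matches_independent_oracle(self):
        from Bio.SeqUtils import molecular_weight

        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(AA, size=100))
            # mass tables differ in the 4th significant digit per residue
            assert compute_mw(seq) * 1000 == pytest.approx(
                molecular_weight(seq, seq_type="protein"), rel=5e-5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_additive_up_to_water(self, a, b):
        assert compute_mw(a + b) * 1000 == pytest.approx(
            (compute_mw(a) + compute_mw(b)) * 1000 - 18.02, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_mw("")


class TestIsoelectricPoint:
    def test_charge_vanishes_at_pi_for_random_peptides(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(AA, size=int(rng.integers(10, 80))))
            pi = compute_pi(seq)
            assert abs(net_charge(seq, pi)) < 1e-3

    def test_basic_peptide_above_acidic(self):
        assert compute_pi("K" * 10) > compute_pi("D" * 10)

    def test_charge_brackets_zero(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            seq = "".join(rng.choice(AA, size=40))
            assert net_charge(seq, 0.0) > 0
            assert net_charge(seq, 14.0) < 0

    def test_bjellqvist_set_selectable(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        pi_e = compute_pi(seq, pka_set="emboss")
        pi_b = compute_pi(seq, pka_set="bjellqvist")
        assert pi_e != pi_b  # different conventions, both finite
        assert 0 < pi_b < 14


class TestScreen:
    def test_perfect_recall_and_precision_on_planted_proteome(
            self, proteome, panel_records):
        records, truth = proteome
        results = screen_proteome(records, panel_records)
        passed = {r.protein_id for r in results if r.passed}
        assert passed == set(truth.planted_aqps)  # recall & precision 1.0

    def test_deleting_second_npa_fails_with_reason(self, panel_records):
        seq = sd.subgroup_scaffold("PIP1")
        i = sd.DIAGNOSTIC_COLUMNS["NPA_LE_0"]
        broken = seq[:i] + "GGG" + seq[i + 3:]
        (res,) = screen_proteome([("broken", broken)], panel_records)
        assert not res.passed
        assert "npa_count" in res.fail_reasons

    def test_self_reference_identity_is_one(self, panel_records):
        seq = panel_records[0].sequence
        (res,) = screen_proteome([("self", seq)], panel_records)
        assert res.best_ref_identity == 1.0

    def test_empty_proteome_yields_empty_results(self, panel_records):
        assert screen_proteome([], panel_records) == []

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            screen_proteome([("x", "ACDEF")], [])

    def test_fail_reasons_iff_not_passed(self, proteome, panel_records):
        records, _ = proteome
        for r in screen_proteome(records, panel_records, ScreenConfig()):
            assert r.passed == (len(r.fail_reasons) == 0)
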