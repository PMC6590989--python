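"""Motif scanner: worked examples, oracle equivalence, and pattern properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raftcrac.motifs import (
    CRAC_CANONICAL,
    CRAC_EXTENDED,
    CracMatch,
    MotifPattern,
    ProteinRecord,
    TMTopology,
    read_matches,
    report_matches,
    scan_sequence,
    scan_tm,
    tm_windows,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestScanSequence:
    def test_tm2_fragment_three_overlapping_motifs(self, tm2_fragment):
        """The 780-790 fragment hosts exactly the three printed anchor triples."""
        anchors = [m.anchors for m in scan_sequence(tm2_fragment, CRAC_EXTENDED)]
        assert anchors == [(780, 786, 790), (782, 786, 790), (782, 788, 790)]

    def test_tm4_fragment_single_motif(self, tm4_fragment):
        matches = scan_sequence(tm4_fragment, CRAC_EXTENDED)
        assert [m.anchors for m in matches] == [(850, 852, 855)]
        assert matches[0].matched_subsequence == "LLYLQR"

    def test_canonical_pattern_tyrosine_only(self, tm2_fragment):
        """With Y as the only aromatic anchor, just one triple survives:
        V780→Y788 spans a 7-residue gap exceeding the bound."""
        anchors = [m.anchors for m in scan_sequence(tm2_fragment, CRAC_CANONICAL)]
        assert anchors == [(782, 788, 790)]

    def test_no_anchor_residues_no_matches(self):
        rec = ProteinRecord("poly-A", sequence="AAAAAAA", offset=10)
        assert scan_sequence(rec, CRAC_EXTENDED) == []

    def test_empty_sequence_empty_result(self):
        assert scan_sequence(ProteinRecord("e", sequence=""), CRAC_EXTENDED) == []

    def test_invalid_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="residue 783"):
            ProteinRecord("bad", sequence="VFLB", offset=780)

    def test_region_requires_all_anchors_inside(self, tm2_fragment):
        # region excluding the basic anchor K790 leaves nothing
        assert scan_sequence(tm2_fragment, CRAC_EXTENDED, region=(780, 789)) == []

    def test_region_outside_record_rejected(self, tm2_fragment):
        with pytest.raises(ValueError, match="outside record range"):
            scan_sequence(tm2_fragment, CRAC_EXTENDED, region=(700, 800))

    def test_unknown_residue_matches_no_anchor_but_fills_gaps(self):
        # X in a gap position is fine; X never serves as an anchor
        rec = ProteinRecord("x-gap", sequence="VXXYXXK")
        assert [m.anchors for m in scan_sequence(rec, CRAC_EXTENDED)] == [(1, 4, 7)]
        rec2 = ProteinRecord("x-anchor", sequence="VXXXXXK")
        assert scan_sequence(rec2, CRAC_EXTENDED) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(
        self, seed, brute_scanner, make_random_protein
    ):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            length = int(rng.integers(1, 61))
            seq = make_random_protein(rng, length)
            offset = int(rng.integers(1, 500))
            got = [m.anchors for m in
                   scan_sequence(ProteinRecord("r", sequence=seq, offset=offset))]
            assert got == brute_scanner(seq, offset, CRAC_EXTENDED)

    @given(st.text(alphabet=AA, min_size=0, max_size=40), st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_offset_covariance(self, seq, delta):
        """Shifting the numbering shifts every anchor by exactly the shift."""
        base = scan_sequence(ProteinRecord("a", sequence=seq, offset=1))
        moved = scan_sequence(ProteinRecord("b", sequence=seq, offset=1 + delta))
        assert [tuple(p + delta for p in m.anchors) for m in base] == \
            [m.anchors for m in moved]

    @given(st.text(alphabet=AA, min_size=3, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_enlarging_aromatic_set_never_loses_matches(self, seq):
        rec = ProteinRecord("r", sequence=seq)
        narrow = {m.anchors for m in scan_sequence(rec, CRAC_CANONICAL)}
        wide = {m.anchors for m in scan_sequence(rec, CRAC_EXTENDED)}
        assert narrow <= wide

    def test_enlarging_region_never_loses_matches(self, tm2_fragment):
        inner = {m.anchors
                 for m in scan_sequence(tm2_fragment, CRAC_EXTENDED, (782, 790))}
        outer = {m.anchors
                 for m in scan_sequence(tm2_fragment, CRAC_EXTENDED, (780, 790))}
        assert inner <= outer

    def test_pattern_is_directional(self):
        """Reversing the TM2 fragment must not reproduce the forward motifs."""
        fwd = scan_sequence(ProteinRecord("f", sequence="VFLSSIFGYCK", offset=780))
        rev = scan_sequence(ProteinRecord("r", sequence="KCYGFISSLFV", offset=780))
        assert len(fwd) == 3
        assert {m.anchors for m in rev} != {m.anchors for m in fwd}


class TestTMWindows:
    def test_flank_expansion_with_clipping(self):
        topo = TMTopology([("TM2", 766, 793)])
        assert tm_windows(topo, flank=5, sequence_range=(761, 800)) == \
            [("TM2", 761, 798)]

    def test_left_clip_at_sequence_start(self):
        topo = TMTopology([("S", 1, 10)])
        assert tm_windows(topo, flank=5, sequence_range=(1, 12)) == [("S", 1, 12)]

    def test_zero_flank_is_identity(self):
        topo = TMTopology([("A", 5, 9), ("B", 20, 30)])
        assert tm_windows(topo, flank=0) == [("A", 5, 9), ("B", 20, 30)]

    def test_topology_validation(self):
        with pytest.raises(ValueError, match="start"):
            TMTopology([("bad", 10, 5)])
        with pytest.raises(ValueError, match="sorted"):
            TMTopology([("a", 10, 20), ("b", 15, 25)])


class TestScanTM:
    def test_tm2_count_three_at_zero_flank(self, tm2_fragment):
        topo = TMTopology([("TM2", 780, 790)])
        per = scan_tm(tm2_fragment, topo, CRAC_EXTENDED, flank=0)
        assert len(per["TM2"]) == 3
        assert all(m.segment_id == "TM2" for m in per["TM2"])

    def test_tm4_count_one_at_zero_flank(self, tm4_fragment):
        per = scan_tm(tm4_fragment, TMTopology([("TM4", 850, 855)]), flank=0)
        assert len(per["TM4"]) == 1

    def test_no_basic_residues_all_counts_zero(self):
        rec = ProteinRecord("nb", sequence="VFLSSIFGYCA", offset=1)
        per = scan_tm(rec, TMTopology([("S", 1, 11)]), flank=0)
        assert len(per["S"]) == 0

    def test_segment_outside_record_rejected(self, tm2_fragment):
        with pytest.raises(ValueError, match="outside record"):
            scan_tm(tm2_fragment, TMTopology([("TM", 700, 800)]))

    def test_flank_admits_interface_anchors(self):
        # basic anchor sits one residue past the segment end; only the
        # flanked window picks it up
        rec = ProteinRecord("if", sequence="AVAAYAAKAA", offset=1)
        topo = TMTopology([("TM", 1, 7)])
        assert len(scan_tm(rec, topo, flank=0)["TM"]) == 0
        assert len(scan_tm(rec, topo, flank=5)["TM"]) == 1


class TestReportMatches:
    def test_empty_match_list_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        df = report_matches([], path)
        assert df.empty
        assert path.read_text().strip().startswith("segment_id")

    def test_tm2_rows_all_end_at_basic_anchor(self, tm2_fragment, tmp_path):
        matches = scan_sequence(tm2_fragment, CRAC_EXTENDED)
        df = report_matches(matches, tmp_path / "m.tsv")
        assert len(df) == 3
        assert (df["end"] == 790).all()

    def test_round_trip(self, tm2_fragment, tmp_path):
        topo = TMTopology([("TM2", 780, 790)])
        per = scan_tm(tm2_fragment, topo, flank=0)
        path = tmp_path / "rt.tsv"
        report_matches(per, path)
        back = read_matches(path)
        assert [(m.anchors, m.segment_id, m.matched_subsequence) for m in back] \
            == [(m.anchors, m.segment_id, m.matched_subsequence)
                for m in per["TM2"]]


class TestPatternValidation:
    def test_gap_bounds_checked(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", gap_min=0)
        with pytest.raises(ValueError):
            MotifPattern("bad", gap_min=4, gap_max=2)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", basic_set=frozenset())

    def test_match_invariants_enforced(self):
        with pytest.raises(ValueError):
            CracMatch(10, 5, 20, "X")
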