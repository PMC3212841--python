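"""Phase-2 segmentation, evidence classes and the ORB verdict."""
import numpy as np
import pytest

import lgtnet as L
from lgtnet.breakpoints import (BreakpointCall, call_orb, classify_evidence,
                                nj_candidates, segment_alignment)
from lgtnet.screen import ScreenResult
from lgtnet.spr import random_spr


def _mock_call(supports, incompatible=True):
    t1 = L.parse_newick("((A,B),(C,D),E);")
    t2 = L.parse_newick("((A,C),(B,D),E);") if incompatible else t1
    return BreakpointCall(positions=[100], segment_topologies=[0, 1],
                          segment_supports=list(supports),
                          candidates=[t1, t2])


class TestSegmentation:
    def test_homogeneous_alignment_gives_no_breakpoints(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 10, False, 0, rng)
        aln, _ = L.simulate_alignment([tree], 600, 1.0, (), rng)
        call = segment_alignment(aln, [tree] + nj_candidates(aln))
        assert call.positions == []
        assert classify_evidence(call) == "none"

    def test_single_candidate_never_segments(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 8, False, 0, rng)
        aln, _ = L.simulate_alignment([tree], 300, 1.0, (), rng)
        for penalty in (0.0, 5.0, 1e9):
            call = segment_alignment(aln, [tree], penalty=penalty)
            assert call.positions == []

    def test_infinite_penalty_gives_single_segment(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 10, False, 0, rng)
        donor = random_spr(random_spr(tree, rng), rng)
        aln, _ = L.simulate_alignment([tree, donor], 600, 1.0, [300], rng)
        call = segment_alignment(aln, [tree, donor], penalty=1e9)
        assert call.positions == []

    def test_true_breakpoint_recovered_near_plant(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 12, False, 0, rng)
        donor = tree
        for _ in range(3):
            donor = random_spr(donor, rng)
        aln, _ = L.simulate_alignment([tree, donor], 600, 1.0, [300], rng)
        call = segment_alignment(aln, [tree, donor] + nj_candidates(aln))
        assert call.positions
        assert min(abs(p - 300) for p in call.positions) <= 50

    def test_positions_strictly_inside_alignment(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 10, False, 0, rng)
        donor = random_spr(random_spr(tree, rng), rng)
        aln, _ = L.simulate_alignment([tree, donor], 450, 1.0, [210], rng)
        call = segment_alignment(aln, [tree, donor])
        assert all(0 < p < aln.length for p in call.positions)
        orig = call.original_positions(aln.column_map)
        assert orig == call.positions  # untrimmed: identity map

    def test_empty_candidate_set_rejected(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 8, False, 0, rng)
        aln, _ = L.simulate_alignment([tree], 300, 1.0, (), rng)
        with pytest.raises(ValueError, match="empty"):
            segment_alignment(aln, [])


class TestEvidenceClasses:
    def test_both_flanks_high_support_is_class_A(self):
        assert classify_evidence(_mock_call([0.99, 0.99])) == "A"

    def test_mixed_support_is_class_B(self):
        assert classify_evidence(_mock_call([0.99, 0.60])) == "B"

    def test_both_flanks_moderate_is_class_C(self):
        assert classify_evidence(_mock_call([0.6, 0.7])) == "C"

    def test_compatible_flanking_topologies_never_evidence(self):
        call = BreakpointCall(positions=[], segment_topologies=[0],
                              segment_supports=[1.0])
        assert classify_evidence(call) == "none"

    def test_low_support_is_none(self):
        assert classify_evidence(_mock_call([0.3, 0.99])) == "none"


class TestOrbCall:
    def _screen(self, passed):
        p = 0.01 if passed else 0.5
        return ScreenResult({"phi": p, "nss": p, "maxchi": p})

    def test_passed_screen_and_class_A_is_orb_positive(self):
        call = _mock_call([0.99, 0.99])
        classify_evidence(call)
        assert call_orb(self._screen(True), call) is True

    def test_failed_screen_is_orb_negative_regardless(self):
        call = _mock_call([0.99, 0.99])
        classify_evidence(call)
        assert call_orb(self._screen(False), call) is False
        assert call_orb(self._screen(False), None) is False

    def test_passed_screen_without_evidence_is_orb_negative(self):
        call = _mock_call([0.2, 0.2])
        classify_evidence(call)
        assert call_orb(self._screen(True), call) is False
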