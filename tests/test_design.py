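"""Designer: acceptance rule, design constants, closed-loop verification."""

import random

import pytest

from aptalogic import (Strand, accept_sequence, DesignConstraints,
                       design_interfering_gate, make_core)
from aptalogic.design import sticky_overlap


class TestAcceptSequence:
    def test_poly_a_with_open_chain_target_is_accepted(self, cond):
        ok, rep = accept_sequence([Strand("pa", "RNA", "A" * 18)], (), (),
                                  cond)
        assert ok and rep.mfe_matches_target and rep.dG_mfe == 0.0

    def test_structured_sequence_fails_open_chain_target(self, cond):
        ok, _ = accept_sequence(
            [Strand("hp", "RNA", "GGCGCCAAAAGGCGCC")], (), (), cond)
        assert not ok

    def test_missing_target_pair_reported(self, cond):
        s = Strand("pa", "RNA", "A" * 12 + "GGGCCC")
        ok, rep = accept_sequence([s], {(0, 11)}, (), cond)
        assert not ok
        assert rep.missing_pairs == ((0, 11),)

    def test_gap_threshold_comparison(self, cond, fixture_set):
        """A sequence whose best competitor sits below the configured gap
        fraction is rejected, and accepted once the demand drops."""
        core = fixture_set.interfering.core
        probe = Strand("c", "RNA", core.sequence)
        target = core.on_pairs(0)
        pocket = core.motif("c").pocket_positions
        ok, rep = accept_sequence([probe], target, pocket, cond)
        assert ok  # shipped cores pass at the default 20 % rule
        stricter = DesignConstraints(
            energy_gap_fraction=min(0.95, rep.gap_fraction + 0.05))
        ok2, _ = accept_sequence([probe], target, pocket, cond, stricter)
        assert not ok2
        looser = DesignConstraints(
            energy_gap_fraction=rep.gap_fraction / 2)
        ok3, _ = accept_sequence([probe], target, pocket, cond, looser)
        assert ok3


class TestDesignConstants:
    def test_defaults_carry_the_printed_design_constants(self):
        cons = DesignConstraints()
        assert cons.operating_temp == 22.0
        assert cons.input_len_range == (15, 27)
        assert cons.energy_gap_fraction == 0.20
        assert cons.sticky_len == 17
        assert cons.inhibitor_loop_len == 8
        assert cons.and_tm_window == (0.0, 10.0)
        assert cons.or_tm_margin == 15.0

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            DesignConstraints(energy_gap_fraction=1.5)
        with pytest.raises(ValueError):
            DesignConstraints(input_len_range=(10, 5))
        with pytest.raises(ValueError):
            DesignConstraints(sticky_len=40)


class TestFixtureGeometry:
    def test_all_simple_gate_inputs_within_length_range(self, fixture_set):
        lo, hi = DesignConstraints().input_len_range
        for gate in fixture_set.gates.values():
            assert lo <= len(gate.input_a) <= hi
            assert lo <= len(gate.input_b) <= hi

    def test_and_or_share_identical_gate_rna(self, fixture_set):
        and_rna = fixture_set.gates["AND"].gate_strands[0].sequence
        or_rna = fixture_set.gates["OR"].gate_strands[0].sequence
        assert and_rna == or_rna

    def test_nand_nor_share_identical_gate_rna(self, fixture_set):
        assert fixture_set.gates["NAND"].gate_strands[0].sequence == \
            fixture_set.gates["NOR"].gate_strands[0].sequence

    def test_or_inputs_are_longer_than_and_inputs(self, fixture_set):
        assert len(fixture_set.gates["OR"].input_a) > \
            len(fixture_set.gates["AND"].input_a)
        assert len(fixture_set.gates["OR"].input_b) > \
            len(fixture_set.gates["AND"].input_b)

    def test_and_tm_window_and_or_margin(self, fixture_set):
        cons = DesignConstraints()
        rep = fixture_set.interfering.report
        for tm in rep["tm_and"]:
            assert cons.operating_temp + cons.and_tm_window[0] < tm \
                <= cons.operating_temp + cons.and_tm_window[1]
        for tm in rep["tm_or"]:
            assert tm >= cons.operating_temp + cons.or_tm_margin

    def test_sticky_handshake_is_exactly_17(self, fixture_set):
        gs = fixture_set.inhibitor_set
        assert sticky_overlap(gs.input_a, gs.input_b) == 17

    def test_xor_inhibitor_has_two_8nt_loops(self, fixture_set):
        rep = fixture_set.inhibitor_set.report
        segs = rep["segments"]
        assert segs["l1"][1] - segs["l1"][0] == 8
        assert segs["l2"][1] - segs["l2"][0] == 8

    def test_nand_runs_at_double_input_stoichiometry(self, fixture_set):
        assert fixture_set.gates["NAND"].input_multiplier == 2.0
        for name in ("AND", "OR", "NOR"):
            assert fixture_set.gates[name].input_multiplier == 1.0

    def test_noninterfering_gate_accepted_in_no_input_state(
            self, fixture_set, cond):
        """The shipped NAND/NOR gate RNA passes the full acceptance rule:
        its no-input MFE realizes the ON conformation and no
        conformation-breaking refold comes within the 20 % window."""
        pair = fixture_set.noninterfering
        motif = pair.nand_gate.motif
        ok, rep = accept_sequence([pair.gate_strand], motif.required_pairs,
                                  motif.pocket_positions, cond)
        assert rep.mfe_matches_target
        assert ok, f"gap fraction {rep.gap_fraction}"

    def test_interfering_gate_off_state_matches_design(self, fixture_set):
        """The AND/OR gate RNA's no-input MFE realizes the designed OFF
        conformation.  Its energy gap to the partial-ON refold is
        positive but deliberately small — that refold is the switching
        transition the inputs drive — so the 20 % rule is applied to the
        core in isolation, not to the assembled switch."""
        rep = fixture_set.interfering.report["off_state"]
        assert rep.mfe_matches_target
        assert rep.gap_fraction is not None and rep.gap_fraction > 0


class TestDeterminism:
    def test_same_seed_reproduces_identical_design(self, cond):
        cons = DesignConstraints(max_redesign_rounds=40)
        rng1 = random.Random(1000)
        core1 = make_core(rng1)
        pair1 = design_interfering_gate(core1, cons, cond, rng=rng1)
        rng2 = random.Random(1000)
        core2 = make_core(rng2)
        pair2 = design_interfering_gate(core2, cons, cond, rng=rng2)
        assert core1 == core2
        assert pair1.gate_strand == pair2.gate_strand
        assert pair1.and_gate.input_a == pair2.and_gate.input_a
        assert pair1.or_gate.input_b == pair2.or_gate.input_b
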