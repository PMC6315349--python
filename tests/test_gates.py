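"""Gate models: ON-state detection, readout, classification, truth tables."""

import pytest

from aptalogic import (AptamerMotif, GateSpec, MG_REPORTER, DFHBI_REPORTER,
                       ReporterSpec, Strand, classify_output,
                       fluorescence_signal, fold_mfe, is_on_state)
from aptalogic.gates import GateValidationError, on_copy_count
from aptalogic.structure import from_dot_bracket
from aptalogic.tube import ComplexSpecies, TubeState


@pytest.fixture()
def hairpin_motif():
    # 6-bp stem, positions 6-9 are the pocket (loop must stay open)
    return AptamerMotif("hp", (0, 15),
                        frozenset({(1, 14), (3, 12)}),
                        frozenset({7, 8}))


@pytest.fixture()
def hairpin():
    return Strand("hp", "RNA", "GGCGCC" + "AAAA" + "GGCGCC")


class TestMotif:
    def test_required_pairs_must_lie_in_core_span(self):
        with pytest.raises(GateValidationError):
            AptamerMotif("x", (0, 5), frozenset({(1, 10)}),
                         frozenset({2}))

    def test_pocket_cannot_overlap_required_pairs(self):
        with pytest.raises(GateValidationError):
            AptamerMotif("x", (0, 10), frozenset({(1, 9)}),
                         frozenset({1}))


class TestOnState:
    def test_folded_hairpin_is_on(self, cond, hairpin, hairpin_motif):
        m = fold_mfe(hairpin, cond)
        assert is_on_state(m, hairpin_motif)

    def test_missing_single_required_pair_is_off(self, hairpin,
                                                 hairpin_motif):
        st = from_dot_bracket([hairpin], ".(..........)...")
        # pair (1,12) is not the required (3,12) partner: OFF
        assert not is_on_state(st, hairpin_motif)
        full = from_dot_bracket([hairpin], "((((((....))))))")
        assert is_on_state(full, hairpin_motif)

    def test_paired_pocket_is_off(self, hairpin, hairpin_motif, cond):
        other = hairpin.reverse_complement("anti", polymer="DNA")
        duplex = from_dot_bracket(
            [hairpin, other], "(" * 16 + "&" + ")" * 16)
        assert not is_on_state(duplex, hairpin_motif)

    def test_unknown_strand_errors(self, hairpin, hairpin_motif, cond):
        other = Strand("zz", "RNA", "ACGUACGU")
        st = from_dot_bracket([other], "." * 8)
        with pytest.raises(GateValidationError):
            is_on_state(st, hairpin_motif)


def _tube_with_on_fraction(hairpin, frac, cond):
    """Synthetic tube: `frac` of the gate strand in the ON fold."""
    on = ComplexSpecies((("hp", 1),),
                        from_dot_bracket([hairpin], "((((((....))))))",
                                         dg=-10.0), -10.0)
    off = ComplexSpecies((("hp", 1),),
                         from_dot_bracket([hairpin], "." * 16, dg=0.0),
                         0.0)
    return TubeState((on, off), (frac * 1e-6, (1 - frac) * 1e-6), cond)


class TestFluorescence:
    def test_all_off_gives_free_dye_baseline(self, cond, hairpin,
                                             hairpin_motif):
        tube = _tube_with_on_fraction(hairpin, 0.0, cond)
        assert fluorescence_signal(tube, hairpin_motif,
                                   MG_REPORTER) == pytest.approx(1.0)

    def test_all_on_gives_enhancement_factor(self, cond, hairpin,
                                             hairpin_motif):
        tube = _tube_with_on_fraction(hairpin, 1.0, cond)
        assert fluorescence_signal(tube, hairpin_motif, MG_REPORTER) == \
            pytest.approx(MG_REPORTER.enhancement_factor)

    def test_half_on_interpolates_linearly(self, cond, hairpin,
                                           hairpin_motif):
        reporter = ReporterSpec("MG", 615, 650, enhancement_factor=101.0,
                                threshold_percent=60.0)
        tube = _tube_with_on_fraction(hairpin, 0.5, cond)
        assert fluorescence_signal(tube, hairpin_motif,
                                   reporter) == pytest.approx(51.0)

    def test_absent_gate_strand_errors(self, cond, hairpin_motif):
        other = Strand("zz", "DNA", "ACGTACGT")
        sp = ComplexSpecies((("zz", 1),),
                            from_dot_bracket([other], "." * 8, dg=0.0),
                            0.0)
        tube = TubeState((sp,), (1e-6,), cond)
        with pytest.raises(GateValidationError):
            fluorescence_signal(tube, hairpin_motif, MG_REPORTER)


class TestClassification:
    def test_equality_at_threshold_reads_zero(self):
        assert classify_output(60.0, MG_REPORTER) == 0

    def test_strictly_above_threshold_reads_one(self):
        assert classify_output(60.0 + 1e-9, MG_REPORTER) == 1
        assert classify_output(100.0, MG_REPORTER) == 1

    def test_zero_reads_zero(self):
        assert classify_output(0.0, MG_REPORTER) == 0

    def test_dfhbi_threshold_is_40(self):
        assert classify_output(41.0, DFHBI_REPORTER) == 1
        assert classify_output(40.0, DFHBI_REPORTER) == 0

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(GateValidationError):
            classify_output(120.0, MG_REPORTER)


class TestGateSpecInvariants:
    def test_inputs_must_be_dna(self, fixture_set):
        g = fixture_set.gates["AND"]
        rna_input = Strand("bad", "RNA",
                           g.input_a.sequence.replace("T", "U"))
        with pytest.raises(GateValidationError):
            GateSpec(g.logic, g.gate_strands, g.motif, rna_input,
                     g.input_b, g.reporter)

    def test_simple_gates_forbid_inhibitor(self, fixture_set):
        g = fixture_set.gates["NOR"]
        with pytest.raises(GateValidationError):
            GateSpec("NOR", g.gate_strands, g.motif, g.input_a, g.input_b,
                     g.reporter, inhibitor=Strand("i", "DNA", "ACGT"))

    def test_xor_requires_inhibitor(self, fixture_set):
        g = fixture_set.inhibitor_set.xor_gate
        with pytest.raises(GateValidationError):
            GateSpec("XOR", g.gate_strands, g.motif, g.input_a, g.input_b,
                     g.reporter, inhibitor=None)


class TestTruthTables:
    def test_normalization_peaks_at_exactly_100(self, fixture_truth):
        for tt in fixture_truth.values():
            assert max(tt.normalized_percent) == 100.0
            assert sum(p == 100.0 for p in tt.normalized_percent) == 1

    def test_interfering_gate_is_off_with_no_inputs(self, fixture_set,
                                                    cond):
        """The arm hairpins of the AND/OR gate RNA sequester the core, so
        the no-input MFE is not dye-binding competent."""
        gate = fixture_set.gates["AND"]
        m = fold_mfe(list(gate.gate_strands), cond)
        assert not is_on_state(m, gate.motif)

    def test_noninterfering_gate_is_on_with_no_inputs(self, fixture_set,
                                                      cond):
        gate = fixture_set.gates["NAND"]
        m = fold_mfe(list(gate.gate_strands), cond)
        assert is_on_state(m, gate.motif)

    def test_on_copy_count_over_complex(self, fixture_set, cond):
        gate = fixture_set.gates["NAND"]
        m = fold_mfe(list(gate.gate_strands), cond)
        assert on_copy_count(m, gate.motif) == (1, 1)
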