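"""Duplex energetics and two-state melting against hand-summed values.

Expected numbers are recomputed in the tests directly from the shipped
nearest-neighbor tables, independently of the implementation's summation.
"""

import math

import pytest

from aptalogic import (Conditions, DuplexError, Strand, TmDomainError,
                       duplex_energy, load_params, melting_temperature)
from aptalogic.params import R_GAS, salt_entropy_per_step


@pytest.fixture(scope="module")
def params():
    return load_params()


def hand_duplex(top: Strand, bottom: Strand, cond, params):
    """Independent two-state sum for a perfect full-length duplex."""
    table = params.table_for(top.polymer, bottom.polymer)
    dh, ds = table.init
    salt = salt_entropy_per_step(cond.sodium_equivalent)
    b = bottom.sequence[::-1]   # aligned antiparallel under the top strand
    for i in range(len(top) - 1):
        h, s = table.stack(f"{top.sequence[i]}{top.sequence[i + 1]}/"
                           f"{b[i]}{b[i + 1]}")
        dh += h
        ds += s + salt
    for i in (0, len(top) - 1):
        if top.sequence[i] in "AUT" or b[i] in "AUT":
            h, s = table.terminal_weak
            dh += h
            ds += s
    return dh, ds


class TestDuplexEnergy:
    def test_two_bp_helix_equals_manual_table_sum(self, cond, params):
        """A 2-bp duplex is one stack plus initiation plus terminals."""
        a = Strand("a", "RNA", "GA")
        b = Strand("b", "RNA", "UC")
        e = duplex_energy(a, b, register=0, cond=cond)
        dh, ds = hand_duplex(a, b, cond, params)
        assert e.dH == pytest.approx(dh, abs=1e-12)
        assert e.dS == pytest.approx(ds, abs=1e-12)
        assert e.dG == pytest.approx(dh - cond.kelvin * ds / 1000, abs=1e-9)

    def test_appending_gc_pair_stabilizes(self, cond):
        """Every G·C extension strictly lowers the duplex free energy."""
        seq = "GAUAC"
        prev = None
        for ext in ("", "G", "GC", "GCG"):
            top = Strand("t", "RNA", seq + ext)
            bot = top.reverse_complement("b")
            e = duplex_energy(top, bot, register=0, cond=cond)
            if prev is not None:
                assert e.dG < prev
            prev = e.dG

    def test_no_overlap_register_errors(self, cond):
        a = Strand("a", "RNA", "GGGG")
        b = Strand("b", "RNA", "CCCC")
        with pytest.raises(DuplexError):
            duplex_energy(a, b, register=50, cond=cond)

    def test_noncomplementary_strands_error(self, cond):
        a = Strand("a", "RNA", "AAAA")
        b = Strand("b", "RNA", "AAAA")
        with pytest.raises(DuplexError):
            duplex_energy(a, b, register=0, cond=cond)


class TestMeltingTemperature:
    def test_hybrid_15mer_matches_manual_two_state(self, cond, params):
        """RNA/DNA 15-mer at 1 uM per strand vs the closed-form Tm."""
        dna = Strand("inp", "DNA", "ACGTACGTACGTACG")
        rna = dna.reverse_complement("arm", polymer="RNA")
        ct = 2e-6
        tm = melting_temperature(rna, dna, cond, total_concentration=ct)
        dh, ds = hand_duplex(rna, dna, cond, params)
        expected = dh * 1000.0 / (ds + 1000.0 * R_GAS * math.log(ct / 4)) \
            - 273.15
        assert tm == pytest.approx(expected, abs=0.1)

    def test_tm_increases_with_total_concentration(self, cond):
        dna = Strand("inp", "DNA", "ACGTACGTACGTACG")
        rna = dna.reverse_complement("arm", polymer="RNA")
        t1 = melting_temperature(rna, dna, cond, total_concentration=1e-6)
        t2 = melting_temperature(rna, dna, cond, total_concentration=2e-6)
        assert t2 > t1

    def test_tm_increases_with_gc_extension(self, cond):
        """Extending the duplex with G·C pairs raises Tm monotonically."""
        prev = None
        for n in range(0, 4):
            top = Strand("t", "RNA", "GAUACUA" + "GC" * n)
            bot = top.reverse_complement("b")
            tm = melting_temperature(top, bot, cond,
                                     total_concentration=2e-6)
            if prev is not None:
                assert tm > prev
            prev = tm

    def test_concentrations_read_from_conditions(self):
        dna = Strand("inp", "DNA", "ACGTACGTACGTACG")
        rna = dna.reverse_complement("arm", polymer="RNA")
        c = Conditions(concentrations={"inp": 1e-6, "arm": 1e-6})
        assert melting_temperature(rna, dna, c) == pytest.approx(
            melting_temperature(rna, dna, c, total_concentration=2e-6))

    def test_domain_error_when_entropy_term_nonnegative(self, cond):
        """An (unphysical) huge C_T drives dS + R ln(C_T/4) >= 0."""
        a = Strand("a", "DNA", "AT")
        b = a.reverse_complement("b")
        with pytest.raises(TmDomainError):
            melting_temperature(a, b, cond, total_concentration=1e12)
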