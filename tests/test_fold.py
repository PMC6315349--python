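"""MFE folding: exhaustive-oracle agreement, self-consistency, caps."""

import random

import pytest
from hypothesis import given, strategies as st

from aptalogic import (Conditions, FoldResourceError, Strand, fold_mfe,
                       structure_energy)
from _oracle import brute_force_mfe


def rand_strand(rng, name, polymer, lo, hi):
    alphabet = "ACGU" if polymer == "RNA" else "ACGT"
    return Strand(name, polymer,
                  "".join(rng.choice(alphabet)
                          for _ in range(rng.randint(lo, hi))))


class TestBasics:
    def test_poly_a_has_no_structure(self, cond):
        s = fold_mfe(Strand("pa", "RNA", "A" * 20), cond)
        assert s.pairs == frozenset()
        assert s.dG == 0.0

    def test_designed_stem_loop_folds_as_designed(self, cond):
        """A 6-bp stem with a 4-nt loop and no competing complementarity
        recovers all six stem pairs in the MFE."""
        s = Strand("hp", "RNA", "GGCGCC" + "AAAA" + "GGCGCC")
        m = fold_mfe(s, cond)
        assert {(i, 15 - i) for i in range(6)} <= set(m.pairs)

    def test_self_consistency_exact(self, cond):
        s = Strand("x", "RNA", "GGACUCGGAAACCGAGUCC")
        m = fold_mfe(s, cond)
        assert structure_energy(m, cond) == m.dG

    def test_determinism_bit_identical(self, cond):
        s = Strand("x", "RNA", "GCAUCGGCAUAUGCCGAUGC")
        m1 = fold_mfe(s, cond)
        m2 = fold_mfe(s, cond)
        assert m1.pairs == m2.pairs
        assert m1.dG == m2.dG

    def test_length_cap(self, cond):
        s = Strand("big", "RNA", "A" * 50)
        with pytest.raises(FoldResourceError):
            fold_mfe(s, cond, max_len=40)

    def test_strand_count_cap(self, cond):
        ss = [Strand(f"s{i}", "RNA", "ACGU") for i in range(4)]
        with pytest.raises(FoldResourceError):
            fold_mfe(ss, cond)

    def test_forbidden_pair_respected(self, cond):
        s = Strand("hp", "RNA", "GGCGCC" + "AAAA" + "GGCGCC")
        m = fold_mfe(s, cond, forbid_pairs=[(2, 13)])
        assert (2, 13) not in m.pairs
        assert m.dG > fold_mfe(s, cond).dG

    def test_forbidden_position_left_unpaired(self, cond):
        s = Strand("hp", "RNA", "GGCGCC" + "AAAA" + "GGCGCC")
        m = fold_mfe(s, cond, forbid_positions=[3])
        assert all(3 not in p for p in m.pairs)


class TestOracleEquivalence:
    """The DP minimum must equal the exhaustive enumeration minimum."""

    @pytest.mark.parametrize("trial", range(40))
    def test_random_single_strands(self, cond, trial):
        rng = random.Random(500 + trial)
        s = rand_strand(rng, "r", "RNA", 5, 16)
        m = fold_mfe(s, cond)
        _, oe = brute_force_mfe(s, cond)
        assert m.dG == pytest.approx(oe, abs=1e-9)

    @pytest.mark.parametrize("trial", range(15))
    def test_random_two_strand_hybrids(self, cond, trial):
        rng = random.Random(900 + trial)
        a = rand_strand(rng, "a", "RNA", 4, 8)
        b = rand_strand(rng, "b", "DNA", 4, 8)
        m = fold_mfe([a, b], cond)
        _, oe = brute_force_mfe([a, b], cond)
        assert m.dG == pytest.approx(oe, abs=1e-9)

    @pytest.mark.parametrize("trial", range(8))
    def test_random_three_strand_complexes(self, cond, trial):
        rng = random.Random(1300 + trial)
        ss = [rand_strand(rng, f"s{k}", "RNA", 3, 6) for k in range(3)]
        m = fold_mfe(ss, cond)
        _, oe = brute_force_mfe(ss, cond)
        assert m.dG == pytest.approx(oe, abs=1e-9)


class TestProperties:
    @given(st.text(alphabet="ACGU", min_size=1, max_size=12))
    def test_mfe_never_above_open_chain(self, seq):
        """The open chain is always available, so MFE <= 0."""
        m = fold_mfe(Strand("h", "RNA", seq), Conditions())
        assert m.dG <= 1e-12

    @given(st.text(alphabet="ACGU", min_size=4, max_size=11))
    def test_mfe_matches_oracle(self, seq):
        s = Strand("h", "RNA", seq)
        cond = Conditions()
        m = fold_mfe(s, cond)
        _, oe = brute_force_mfe(s, cond)
        assert m.dG == pytest.approx(oe, abs=1e-9)

    @given(st.floats(min_value=10.0, max_value=40.0))
    def test_temperature_moves_energy_continuously(self, temp):
        s = Strand("hp", "RNA", "GGCGCCAAAAGGCGCC")
        m = fold_mfe(s, Conditions(temperature=temp))
        assert m.dG < 0  # the designed stem survives across this range
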