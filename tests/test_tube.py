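"""Complex enumeration and equilibrium concentrations."""

import math
import random

import numpy as np
import pytest

from aptalogic import (ComplexSpecies, Strand, enumerate_complexes,
                       solve_equilibrium)
from aptalogic.params import R_GAS
from aptalogic.tube import TubeError


def closed_form_dimer(k, at, bt):
    """Positive root of K = x / ((at-x)(bt-x))."""
    roots = np.roots([k, -(k * (at + bt) + 1.0), k * at * bt])
    return min(r.real for r in roots
               if abs(r.imag) < 1e-18
               and 0 < r.real <= min(at, bt) * (1 + 1e-9))


class TestEnumeration:
    def test_cap_out_of_range(self, cond):
        s = Strand("a", "DNA", "ACGT")
        with pytest.raises(TubeError):
            enumerate_complexes([s], 0, cond)
        with pytest.raises(TubeError):
            enumerate_complexes([s], 5, cond)

    def test_single_strand_cap_one(self, cond):
        out = enumerate_complexes([Strand("a", "DNA", "ACGTA")], 1, cond)
        assert len(out) == 1 and out[0].name == "a"

    def test_complementary_pair_gives_three_species(self, cond):
        """Two fully complementary strands: both monomers plus the
        heterodimer (homodimers fold with no inter-strand pairs)."""
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        out = enumerate_complexes([a, b], 2, cond)
        assert {sp.name for sp in out} == {"a", "b", "a+b"}

    def test_species_require_interstrand_pairing(self, cond):
        a = Strand("a", "DNA", "AAAAA")
        b = Strand("b", "DNA", "CACAC")
        out = enumerate_complexes([a, b], 2, cond)
        assert {sp.name for sp in out} == {"a", "b"}


class TestEquilibrium:
    def test_monomers_only_recover_totals(self, cond):
        a = Strand("a", "DNA", "AAAAA")
        b = Strand("b", "DNA", "CACAC")
        species = enumerate_complexes([a, b], 2, cond)
        tube = solve_equilibrium(species, {"a": 1e-6, "b": 3e-6}, cond)
        assert tube.concentration_of("a") == pytest.approx(1e-6, rel=1e-9)
        assert tube.concentration_of("b") == pytest.approx(3e-6, rel=1e-9)

    def test_dimerization_matches_closed_form(self, cond):
        """A + B <-> AB with unstructured monomers reproduces the
        quadratic solution to better than 1e-9 M."""
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        species = enumerate_complexes([a, b], 2, cond)
        at, bt = 1e-6, 1.7e-6
        tube = solve_equilibrium(species, {"a": at, "b": bt}, cond)
        dg = {sp.name: sp.dG for sp in species}
        k = math.exp(-(dg["a+b"] - dg["a"] - dg["b"])
                     / (R_GAS * cond.kelvin))
        assert tube.concentration_of("a+b") == pytest.approx(
            closed_form_dimer(k, at, bt), abs=1e-9)

    @pytest.mark.parametrize("trial", range(8))
    def test_mass_conservation_on_random_tubes(self, cond, trial):
        rng = random.Random(60 + trial)
        strands = [
            Strand(f"s{k}", "DNA",
                   "".join(rng.choice("ACGT")
                           for _ in range(rng.randint(6, 12))))
            for k in range(3)
        ]
        species = enumerate_complexes(strands, 3, cond)
        totals = {s.name: rng.uniform(0.2, 5.0) * 1e-6 for s in strands}
        tube = solve_equilibrium(species, totals, cond)
        for name, total in totals.items():
            assert tube.strand_total(name) == pytest.approx(total,
                                                            rel=1e-6)
        assert all(c >= 0 for c in tube.concentrations)

    def test_order_invariance(self, cond):
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        species = enumerate_complexes([a, b], 2, cond)
        totals = {"a": 1e-6, "b": 2e-6}
        t1 = solve_equilibrium(species, totals, cond)
        t2 = solve_equilibrium(list(reversed(species)), totals, cond)
        for sp in species:
            assert t1.concentration_of(sp.name) == pytest.approx(
                t2.concentration_of(sp.name), rel=1e-9)

    def test_stabilizing_a_complex_raises_its_concentration(self, cond):
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        species = enumerate_complexes([a, b], 2, cond)
        totals = {"a": 1e-6, "b": 1e-6}
        base = solve_equilibrium(species, totals, cond)

        def strengthened(sp):
            if sp.name != "a+b":
                return sp
            return ComplexSpecies(sp.strand_counts,
                                  sp.structure.with_dg(sp.dG - 2.0),
                                  sp.dG - 2.0)

        boosted = solve_equilibrium([strengthened(sp) for sp in species],
                                    totals, cond)
        assert boosted.concentration_of("a+b") > \
            base.concentration_of("a+b")

    def test_missing_strand_total_rejected(self, cond):
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        species = enumerate_complexes([a, b], 2, cond)
        with pytest.raises(TubeError):
            solve_equilibrium(species, {"a": 1e-6}, cond)

    def test_csv_dump_has_all_species(self, cond):
        a = Strand("a", "DNA", "AGAGAGAGAG")
        b = a.reverse_complement("b")
        species = enumerate_complexes([a, b], 2, cond)
        tube = solve_equilibrium(species, {"a": 1e-6, "b": 1e-6}, cond)
        frame = tube.to_frame()
        assert list(frame.columns) == ["species", "n_strands",
                                       "dG_kcal_mol", "concentration_M",
                                       "structure"]
        assert len(frame) == len(species)
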