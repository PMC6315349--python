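"""Deterministic fixture generation: the bundled gate and half-adder set.

The exact oligonucleotide sequences used in the original bench work are
not available, so the package ships a generator that produces complete,
verified stand-in sequence sets satisfying every architectural constraint
(input lengths 15-27 nt, 17-nt sticky ends, 8-nt inhibitor loops, shared
gate RNAs, Tm windows, five-strand tetragon, 2:1 inhibitor ratio).  The
same seed and generator version always reproduce byte-identical
sequences, and every fixture passes its closed-loop truth-table check at
generation time.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .design import (DesignConstraints, DesignFailure, InhibitorGateSet,
                     InterferingGatePair, NonInterferingGatePair,
                     accept_sequence, design_inhibitor_pair,
                     design_interfering_gate, design_noninterfering_gate,
                     make_core)
from .halfadder import NanoparticleComplex, assemble_half_adder
from .params import NearestNeighborParams, load_params
from .strands import Conditions, Strand, fasta_string

DEFAULT_SEED = 2018
GENERATOR_VERSION = "aptalogic-fixtures-1"


class FixtureGenerationError(RuntimeError):
    """No verified fixture set found within the attempt budget."""


@dataclass(frozen=True)
class FixtureSet:
    """Verified gates (AND/OR/NAND/NOR), half adder, and provenance."""

    interfering: InterferingGatePair
    noninterfering: NonInterferingGatePair
    inhibitor_set: InhibitorGateSet
    half_adder: NanoparticleComplex
    seed: int
    generator_version: str

    @property
    def gates(self) -> dict:
        return {
            "AND": self.interfering.and_gate,
            "OR": self.interfering.or_gate,
            "NAND": self.noninterfering.nand_gate,
            "NOR": self.noninterfering.nor_gate,
        }

    def all_strands(self) -> list:
        seen, out = set(), []
        for gate in self.gates.values():
            for s in (*gate.gate_strands, gate.input_a, gate.input_b):
                if s.name not in seen:
                    seen.add(s.name)
                    out.append(s)
        gs = self.inhibitor_set
        for s in (*self.half_adder.rna_strands, gs.xor_arm, gs.and_arm,
                  gs.xor_inhibitor, gs.and_inhibitor, gs.input_a,
                  gs.input_b):
            if s.name not in seen:
                seen.add(s.name)
                out.append(s)
        return out

    def to_fasta(self) -> str:
        return fasta_string(self.all_strands())


def _accepted_core(rng, cond, cons, params):
    """Draw cores until one passes the acceptance rule in isolation."""
    for _ in range(200):
        core = make_core(rng)
        probe = Strand("_core_probe", "RNA", core.sequence)
        ok, _rep = accept_sequence(
            [probe], core.on_pairs(0),
            core.motif("_core_probe").pocket_positions, cond, cons, params)
        if ok:
            return core
    raise FixtureGenerationError("no acceptable aptamer core in 200 draws")


def generate_fixtures(seed: int = DEFAULT_SEED,
                      constraints: DesignConstraints | None = None,
                      cond: Conditions | None = None,
                      params: NearestNeighborParams | None = None,
                      max_family_attempts: int = 25) -> FixtureSet:
    """Generate and verify the full fixture set for a seed.

    Each gate family retries with fresh cores until its designer
    succeeds; all randomness flows from the single seeded generator, so
    the result is deterministic per (seed, generator version).
    """
    cond = cond or Conditions()
    params = params or load_params()
    constraints = constraints or DesignConstraints(rng_seed=seed)
    # generation favors fresh cores over deep per-core searches
    constraints = replace(constraints, max_redesign_rounds=min(
        constraints.max_redesign_rounds, 40))
    rng = random.Random(seed)

    def family(designer, n_cores, prefix):
        last = None
        for _ in range(max_family_attempts):
            try:
                cores = [_accepted_core(rng, cond, constraints, params)
                         for _ in range(n_cores)]
                return designer(*cores, constraints, cond, params, rng)
            except DesignFailure as exc:
                last = exc
        raise FixtureGenerationError(
            f"{prefix}: no verified design in {max_family_attempts} "
            f"family attempts (last: {last})")

    interfering = family(
        lambda c, cons, cd, p, r: design_interfering_gate(
            c, cons, cd, p, r, name_prefix="ANDOR"),
        1, "interfering")
    noninterfering = family(
        lambda c, cons, cd, p, r: design_noninterfering_gate(
            c, cons, cd, p, r, name_prefix="NANDNOR"),
        1, "non-interfering")
    inhibitors = family(
        lambda cx, cm, cons, cd, p, r: design_inhibitor_pair(
            cx, cm, cons, cd, p, r, name_prefix="HA"),
        2, "inhibitor")
    particle = assemble_half_adder(inhibitors, rng)
    return FixtureSet(interfering, noninterfering, inhibitors, particle,
                      seed, GENERATOR_VERSION)
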