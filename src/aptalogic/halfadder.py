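"""Tetragon-scaffolded RNA half adder.

The particle self-assembles from five RNA strands: four vertex strands,
each carrying one light-up aptamer arm on alternating vertices (two
MG-type arms for the CARRY/AND channel at 650 nm, two Broccoli-type arms
for the SUM/XOR channel at 510 nm), plus one hub strand closing the
square scaffold.  Each aptamer arm is held OFF by its DNA inhibitor
(AND_DNA and XOR_DNA, two copies each per tetragon); the two shared DNA
inputs switch the channels so that SUM = A XOR B and CARRY = A AND B.

Readout treats the four arms as independent thermodynamic subsystems:
the scaffold is an inert duplex frame with no complementarity to inputs
or inhibitors (checked at assembly), so each channel is evaluated as its
aptamer arm + inhibitor + inputs in a tube at the per-arm stoichiometry.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd

from .design import InhibitorGateSet, _rand_gc_seq, _rc
from .gates import SCENARIOS, TruthTableResult, evaluate_truth_table
from .params import NearestNeighborParams, load_params
from .strands import Conditions, Strand


class HalfAdderValidationError(ValueError):
    """Particle violates the five-strand / 2:1-inhibitor architecture."""


@dataclass(frozen=True)
class NanoparticleComplex:
    """The assembled tetragon: five RNA strands, four aptamer arms on
    alternating vertices, and two copies of each DNA inhibitor."""

    rna_strands: tuple           # 5 Strands (4 vertices + hub)
    arm_channels: tuple          # channel per vertex, e.g. ("MG","DFHBI",..)
    gates: InhibitorGateSet      # arms, inhibitors, shared inputs
    inhibitor_copies: int = 2    # per inhibitor type per tetragon

    def __post_init__(self) -> None:
        if len(self.rna_strands) != 5:
            raise HalfAdderValidationError(
                f"half adder needs exactly 5 RNA strands, got "
                f"{len(self.rna_strands)}")
        for s in self.rna_strands:
            if s.polymer != "RNA":
                raise HalfAdderValidationError(
                    f"scaffold strand {s.name} must be RNA")
        if len(self.arm_channels) != 4 or \
                self.arm_channels.count("MG") != 2 or \
                self.arm_channels.count("DFHBI") != 2:
            raise HalfAdderValidationError(
                "four arms required: two MG and two DFHBI")
        for i in range(4):
            if self.arm_channels[i] == self.arm_channels[(i + 1) % 4]:
                raise HalfAdderValidationError(
                    "aptamer arms must alternate on the vertices")
        if self.inhibitor_copies != 2:
            raise HalfAdderValidationError(
                "inhibitor : tetragon ratio must be 2 : 1 per type")


@dataclass(frozen=True)
class HalfAdderResult:
    """Two-channel truth table: SUM (510 nm) and CARRY (650 nm)."""

    sum_table: TruthTableResult    # XOR / DFHBI channel
    carry_table: TruthTableResult  # AND / MG channel

    @property
    def sum_bits(self) -> tuple:
        return self.sum_table.output_bits

    @property
    def carry_bits(self) -> tuple:
        return self.carry_table.output_bits

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": SCENARIOS,
            "SUM_510nm_percent": self.sum_table.normalized_percent,
            "SUM_bit": self.sum_bits,
            "CARRY_650nm_percent": self.carry_table.normalized_percent,
            "CARRY_bit": self.carry_bits,
        })


def _max_complementary_run(a: str, pa: str, b: str, pb: str) -> int:
    """Longest perfect WC-complementary run between two sequences."""
    from .strands import can_pair
    best = 0
    rb = b[::-1]
    for off in range(-(len(a) - 1), len(rb)):
        run = 0
        for i in range(len(a)):
            j = i + off
            if 0 <= j < len(rb) and can_pair(a[i], rb[j], pa, pb,
                                             wobble=False):
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def assemble_half_adder(gates: InhibitorGateSet,
                        rng: random.Random | None = None,
                        scaffold_stem_len: int = 10,
                        max_crosstalk_run: int = 5) -> NanoparticleComplex:
    """Build the five-strand tetragon around a verified gate set.

    Scaffold duplex segments are drawn randomly and re-drawn until no
    segment shares a complementary run of ``max_crosstalk_run`` or more
    with any input or inhibitor (the designer's cross-talk check).
    """
    rng = rng or random.Random(7)
    dna = [gates.input_a, gates.input_b, gates.xor_inhibitor,
           gates.and_inhibitor]
    rna_arms = [gates.xor_arm, gates.and_arm]

    def clean_segment() -> str:
        for _ in range(500):
            seg = _rand_gc_seq(rng, scaffold_stem_len, (0.4, 0.6))
            bad = any(
                _max_complementary_run(seg, "RNA", s.sequence, s.polymer)
                >= max_crosstalk_run
                for s in dna + rna_arms)
            if not bad:
                return seg
        raise HalfAdderValidationError(
            "could not draw a cross-talk-free scaffold segment")

    q = [clean_segment() for _ in range(4)]
    arms = [gates.and_arm, gates.xor_arm, gates.and_arm, gates.xor_arm]
    channels = ("MG", "DFHBI", "MG", "DFHBI")
    vertices = []
    for i in range(4):
        seq = q[i] + arms[i].sequence + _rc(q[(i + 1) % 4], "RNA")
        vertices.append(Strand(f"vertex{i + 1}_{channels[i]}", "RNA", seq))
    hub = Strand("hub", "RNA", "".join(_rc(qi, "RNA") for qi in reversed(q)))
    return NanoparticleComplex(tuple(vertices) + (hub,), channels, gates)


def evaluate_half_adder(particle: NanoparticleComplex,
                        cond: Conditions | None = None,
                        params: NearestNeighborParams | None = None
                        ) -> HalfAdderResult:
    """Two-channel truth table of the particle, re-derived from
    thermodynamics channel by channel (arms as independent subsystems,
    2 µM arm sites and inhibitors per 1 µM tetragon, 5 µM inputs)."""
    cond = cond or Conditions()
    params = params or load_params()
    sum_tt = evaluate_truth_table(particle.gates.xor_gate, cond, params)
    carry_tt = evaluate_truth_table(particle.gates.and_gate, cond, params)
    return HalfAdderResult(sum_tt, carry_tt)
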