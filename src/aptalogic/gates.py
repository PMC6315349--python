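"""Gate specifications, ON-state detection, readout, and truth tables.

A light-up aptamer is ON when its dye-binding core is correctly folded:
all structurally required base pairs present and the binding-pocket
positions unpaired.  Fluorescence is modeled as structural gating only —
dye is in excess, so the enhancement over free dye scales linearly with
the equilibrium fraction of gate strands in the ON conformation:

    signal = 1 + (F - 1) · [gate_ON] / [gate_total]

Per experiment the four input scenarios (00, 01, 10, 11) are normalized to
their maximum (=100 %) and thresholded; a normalized intensity strictly
greater than the threshold reads out as logic 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .params import NearestNeighborParams, load_params
from .strands import Conditions, Strand
from .structure import SecondaryStructure
from .tube import TubeState, enumerate_complexes, solve_equilibrium

SCENARIOS = ("00", "01", "10", "11")

TRUTH = {
    "AND": (0, 0, 0, 1),
    "OR": (0, 1, 1, 1),
    "NAND": (1, 1, 1, 0),
    "NOR": (1, 0, 0, 0),
    "XOR": (0, 1, 1, 0),
}


class GateValidationError(ValueError):
    """Gate specification violates its invariants."""


@dataclass(frozen=True)
class AptamerMotif:
    """The ON conformation of a light-up aptamer on one gate strand.

    ``required_pairs`` are strand-local (i, j) base pairs that must be
    present, ``pocket_positions`` strand-local indices that must stay
    unpaired for the dye to bind.
    """

    strand_name: str
    core_span: tuple               # (lo, hi) inclusive strand-local span
    required_pairs: frozenset      # {(i, j)} strand-local
    pocket_positions: frozenset    # {i} strand-local

    def __post_init__(self) -> None:
        lo, hi = self.core_span
        if not self.required_pairs or not self.pocket_positions:
            raise GateValidationError("motif needs required pairs and a pocket")
        for i, j in self.required_pairs:
            if not (lo <= i < j <= hi):
                raise GateValidationError(
                    f"required pair ({i},{j}) outside core span {self.core_span}")
        if not all(lo <= p <= hi for p in self.pocket_positions):
            raise GateValidationError("pocket positions outside core span")
        if self.pocket_positions & {k for ij in self.required_pairs for k in ij}:
            raise GateValidationError("pocket positions overlap required pairs")


@dataclass(frozen=True)
class ReporterSpec:
    """Fluorogenic dye channel: wavelengths, enhancement, threshold."""

    dye: str                       # "MG" | "DFHBI"
    excitation_nm: float
    emission_nm: float
    enhancement_factor: float = 100.0
    threshold_percent: float = 60.0

    def __post_init__(self) -> None:
        if self.dye not in ("MG", "DFHBI"):
            raise GateValidationError(f"unknown dye {self.dye!r}")
        if not (0.0 < self.threshold_percent < 100.0):
            raise GateValidationError("threshold_percent must be in (0, 100)")
        if self.enhancement_factor <= 1.0:
            raise GateValidationError("enhancement_factor must exceed 1")


MG_REPORTER = ReporterSpec("MG", 615.0, 650.0, 100.0, 60.0)
DFHBI_REPORTER = ReporterSpec("DFHBI", 465.0, 510.0, 100.0, 40.0)


@dataclass(frozen=True)
class GateSpec:
    """A complete logic gate: strands, motif, reporter, stoichiometry."""

    logic: str
    gate_strands: tuple            # RNA Strand(s)
    motif: AptamerMotif
    input_a: Strand
    input_b: Strand
    reporter: ReporterSpec
    inhibitor: Strand | None = None
    gate_concentration: float = 1e-6       # M
    input_concentration: float = 2e-6      # M per present input
    input_multiplier: float = 1.0          # e.g. 2 for the 2x NAND recipe
    inhibitor_ratio: float = 2.0           # inhibitor : gate
    max_complex_size: int = 3

    def __post_init__(self) -> None:
        if self.logic not in TRUTH:
            raise GateValidationError(f"unknown logic {self.logic!r}")
        for s in self.gate_strands:
            if s.polymer != "RNA":
                raise GateValidationError(f"gate strand {s.name} must be RNA")
        for s in (self.input_a, self.input_b):
            if s.polymer != "DNA":
                raise GateValidationError(f"input {s.name} must be DNA")
        if self.motif.strand_name not in {s.name for s in self.gate_strands}:
            raise GateValidationError(
                f"motif strand {self.motif.strand_name!r} not among gate strands")
        if self.logic == "XOR" and self.inhibitor is None:
            raise GateValidationError("XOR gates require a DNA inhibitor")
        if self.logic in ("OR", "NAND", "NOR") and self.inhibitor is not None:
            raise GateValidationError(
                f"{self.logic} gates are inhibitor-free by construction")
        if self.inhibitor is not None and self.inhibitor.polymer != "DNA":
            raise GateValidationError("inhibitor must be DNA")

    @property
    def is_displacement(self) -> bool:
        return self.inhibitor is not None

    def with_inputs(self, a: Strand, b: Strand) -> "GateSpec":
        return replace(self, input_a=a, input_b=b)


@dataclass(frozen=True)
class TruthTableResult:
    """Per-scenario signal, normalized percentage, and classified bit."""

    logic: str
    raw_signal: tuple              # 4 floats, scenario order 00,01,10,11
    normalized_percent: tuple
    output_bits: tuple

    @property
    def bits(self) -> tuple:
        return self.output_bits

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": SCENARIOS,
            "raw_signal": self.raw_signal,
            "normalized_percent": self.normalized_percent,
            "output_bit": self.output_bits,
        })


# -- operations -----------------------------------------------------------


def is_on_state(s: SecondaryStructure, motif: AptamerMotif,
                copy_index: int = 0) -> bool:
    """True iff the motif's ON conformation is realized in the structure.

    ``copy_index`` selects among multiple copies of the motif's strand in
    the complex.
    """
    offsets = [off for off, st in zip(s.strand_offsets(), s.strands)
               if st.name == motif.strand_name]
    if not offsets:
        raise GateValidationError(
            f"strand {motif.strand_name!r} not in structure")
    off = offsets[copy_index]
    strand = next(st for st in s.strands if st.name == motif.strand_name)
    if motif.core_span[1] >= len(strand):
        raise GateValidationError("motif core span exceeds strand length")
    pm = s.pair_map()
    for i, j in motif.required_pairs:
        if pm.get(off + i) != off + j:
            return False
    return all(off + p not in pm for p in motif.pocket_positions)


def on_copy_count(s: SecondaryStructure, motif: AptamerMotif) -> tuple:
    """(number of ON copies, total copies) of the motif strand in s."""
    total = sum(1 for st in s.strands if st.name == motif.strand_name)
    on = sum(1 for c in range(total) if is_on_state(s, motif, c))
    return on, total


def fluorescence_signal(tube: TubeState, motif: AptamerMotif,
                        reporter: ReporterSpec) -> float:
    """Fold-enhancement over free dye given the tube's ON fraction."""
    total = on = 0.0
    for sp, conc in zip(tube.species, tube.concentrations):
        copies = sp.count_of(motif.strand_name)
        if not copies:
            continue
        n_on, n_tot = on_copy_count(sp.structure, motif)
        total += n_tot * conc
        on += n_on * conc
    if total <= 0:
        raise GateValidationError(
            f"gate strand {motif.strand_name!r} absent from tube")
    return 1.0 + (reporter.enhancement_factor - 1.0) * (on / total)


def classify_output(normalized_percent: float,
                    reporter: ReporterSpec) -> int:
    """1 iff strictly above the channel threshold (equality reads as 0)."""
    if not (0.0 <= normalized_percent <= 100.0 + 1e-9):
        raise GateValidationError(
            f"normalized percent {normalized_percent} out of [0, 100]")
    return int(normalized_percent > reporter.threshold_percent)


def scenario_totals(gate: GateSpec, scenario: str) -> dict:
    """Per-strand total concentrations (M) for one input scenario."""
    totals = {s.name: gate.gate_concentration for s in gate.gate_strands}
    if gate.inhibitor is not None:
        totals[gate.inhibitor.name] = \
            gate.inhibitor_ratio * gate.gate_concentration
    bit_a, bit_b = int(scenario[0]), int(scenario[1])
    conc = gate.input_concentration * gate.input_multiplier
    if bit_a:
        totals[gate.input_a.name] = conc
    if bit_b:
        totals[gate.input_b.name] = conc
    return totals


def evaluate_truth_table(gate: GateSpec, cond: Conditions | None = None,
                         params: NearestNeighborParams | None = None,
                         species=None) -> TruthTableResult:
    """Simulate all four scenarios end-to-end and classify the outputs.

    Complexes are enumerated once over the full strand set; per scenario,
    species involving absent strands are dropped and the equilibrium
    re-solved.
    """
    cond = cond or Conditions()
    params = params or load_params()
    strands = list(gate.gate_strands) + [gate.input_a, gate.input_b]
    if gate.inhibitor is not None:
        strands.append(gate.inhibitor)
    if species is None:
        species = enumerate_complexes(strands, gate.max_complex_size,
                                      cond, params)

    signals = []
    for scenario in SCENARIOS:
        totals = scenario_totals(gate, scenario)
        present = [sp for sp in species
                   if all(n in totals for n, _ in sp.strand_counts)]
        tube = solve_equilibrium(present, totals, cond)
        signals.append(fluorescence_signal(tube, gate.motif, gate.reporter))

    peak = max(signals)
    # divide first so the peak scenario lands on exactly 100.0
    normalized = tuple(100.0 * (s / peak) for s in signals)
    bits = tuple(classify_output(p, gate.reporter) for p in normalized)
    return TruthTableResult(gate.logic, tuple(signals), normalized, bits)
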