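"""Structured config I/O: gate specs and half-adder specs as YAML.

One human-editable file per gate or circuit.  The schema is versioned and
fail-loud: unknown keys raise, so typos cannot silently change a design.
"""

from __future__ import annotations

import yaml

from .design import CoreDesign, InhibitorGateSet
from .gates import AptamerMotif, GateSpec, ReporterSpec
from .halfadder import NanoparticleComplex
from .strands import Conditions, Strand

SCHEMA_VERSION = 1


class SpecFormatError(ValueError):
    """Malformed or unknown-key spec file."""


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SpecFormatError(f"unknown keys {sorted(unknown)} in {where}")


def _strand_to_dict(s: Strand) -> dict:
    return {"name": s.name, "polymer": s.polymer, "sequence": s.sequence}


def _strand_from_dict(d: dict, where: str) -> Strand:
    _check_keys(d, {"name", "polymer", "sequence"}, where)
    return Strand(d["name"], d["polymer"], d["sequence"])


def gate_to_dict(gate: GateSpec, cond: Conditions | None = None) -> dict:
    cond = cond or Conditions()
    return {
        "schema_version": SCHEMA_VERSION,
        "logic": gate.logic,
        "gate_strands": [_strand_to_dict(s) for s in gate.gate_strands],
        "input_a": _strand_to_dict(gate.input_a),
        "input_b": _strand_to_dict(gate.input_b),
        "inhibitor": (_strand_to_dict(gate.inhibitor)
                      if gate.inhibitor else None),
        "motif": {
            "strand": gate.motif.strand_name,
            "core_span": list(gate.motif.core_span),
            "required_pairs": sorted(map(list, gate.motif.required_pairs)),
            "pocket_positions": sorted(gate.motif.pocket_positions),
        },
        "reporter": {
            "dye": gate.reporter.dye,
            "excitation_nm": gate.reporter.excitation_nm,
            "emission_nm": gate.reporter.emission_nm,
            "enhancement_factor": gate.reporter.enhancement_factor,
            "threshold_percent": gate.reporter.threshold_percent,
        },
        "tube": {
            "temperature_C": cond.temperature,
            "monovalent_M": cond.monovalent,
            "divalent_M": cond.divalent,
            "gate_concentration_M": gate.gate_concentration,
            "input_concentration_M": gate.input_concentration,
            "input_multiplier": gate.input_multiplier,
            "inhibitor_ratio": gate.inhibitor_ratio,
            "max_complex_size": gate.max_complex_size,
        },
    }


def gate_from_dict(d: dict) -> tuple:
    """(GateSpec, Conditions) from a spec mapping (fail-loud)."""
    _check_keys(d, {"schema_version", "logic", "gate_strands", "input_a",
                    "input_b", "inhibitor", "motif", "reporter", "tube"},
                "gate spec")
    if d.get("schema_version") != SCHEMA_VERSION:
        raise SpecFormatError(
            f"unsupported schema_version {d.get('schema_version')!r}")
    m = d["motif"]
    _check_keys(m, {"strand", "core_span", "required_pairs",
                    "pocket_positions"}, "motif")
    motif = AptamerMotif(
        m["strand"], tuple(m["core_span"]),
        frozenset(map(tuple, m["required_pairs"])),
        frozenset(m["pocket_positions"]))
    r = d["reporter"]
    _check_keys(r, {"dye", "excitation_nm", "emission_nm",
                    "enhancement_factor", "threshold_percent"}, "reporter")
    reporter = ReporterSpec(r["dye"], r["excitation_nm"], r["emission_nm"],
                            r["enhancement_factor"], r["threshold_percent"])
    t = d["tube"]
    _check_keys(t, {"temperature_C", "monovalent_M", "divalent_M",
                    "gate_concentration_M", "input_concentration_M",
                    "input_multiplier", "inhibitor_ratio",
                    "max_complex_size"}, "tube")
    cond = Conditions(t["temperature_C"], t["monovalent_M"],
                      t["divalent_M"])
    gate = GateSpec(
        logic=d["logic"],
        gate_strands=tuple(_strand_from_dict(s, "gate_strands")
                           for s in d["gate_strands"]),
        motif=motif,
        input_a=_strand_from_dict(d["input_a"], "input_a"),
        input_b=_strand_from_dict(d["input_b"], "input_b"),
        reporter=reporter,
        inhibitor=(_strand_from_dict(d["inhibitor"], "inhibitor")
                   if d.get("inhibitor") else None),
        gate_concentration=t["gate_concentration_M"],
        input_concentration=t["input_concentration_M"],
        input_multiplier=t["input_multiplier"],
        inhibitor_ratio=t["inhibitor_ratio"],
        max_complex_size=t["max_complex_size"],
    )
    return gate, cond


def write_gate_spec(gate: GateSpec, path, cond: Conditions | None = None):
    with open(path, "w") as fh:
        yaml.safe_dump(gate_to_dict(gate, cond), fh, sort_keys=False)


def read_gate_spec(path) -> tuple:
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SpecFormatError(f"{path}: {exc}") from exc
    if not isinstance(d, dict):
        raise SpecFormatError(f"{path}: not a mapping")
    return gate_from_dict(d)


# -- half adder ------------------------------------------------------------

def _core_to_dict(core: CoreDesign) -> dict:
    return {"a": core.a, "p1": core.p1, "b": core.b, "t": core.t,
            "p2": core.p2}


def half_adder_to_dict(particle: NanoparticleComplex,
                       cond: Conditions | None = None) -> dict:
    g = particle.gates
    return {
        "schema_version": SCHEMA_VERSION,
        "rna_strands": [_strand_to_dict(s) for s in particle.rna_strands],
        "arm_channels": list(particle.arm_channels),
        "inhibitor_copies": particle.inhibitor_copies,
        "xor_core": _core_to_dict(g.xor_core),
        "and_core": _core_to_dict(g.and_core),
        "xor_gate": gate_to_dict(g.xor_gate, cond),
        "and_gate": gate_to_dict(g.and_gate, cond),
    }


def half_adder_from_dict(d: dict) -> tuple:
    """(NanoparticleComplex, Conditions) from a half-adder spec mapping."""
    _check_keys(d, {"schema_version", "rna_strands", "arm_channels",
                    "inhibitor_copies", "xor_core", "and_core",
                    "xor_gate", "and_gate"}, "half-adder spec")
    if d.get("schema_version") != SCHEMA_VERSION:
        raise SpecFormatError(
            f"unsupported schema_version {d.get('schema_version')!r}")
    xor_gate, cond = gate_from_dict(d["xor_gate"])
    and_gate, _ = gate_from_dict(d["and_gate"])
    xor_core = CoreDesign(**d["xor_core"])
    and_core = CoreDesign(**d["and_core"])
    gates = InhibitorGateSet(
        xor_arm=xor_gate.gate_strands[0], and_arm=and_gate.gate_strands[0],
        xor_inhibitor=xor_gate.inhibitor, and_inhibitor=and_gate.inhibitor,
        input_a=xor_gate.input_a, input_b=xor_gate.input_b,
        xor_gate=xor_gate, and_gate=and_gate,
        xor_core=xor_core, and_core=and_core, report={})
    particle = NanoparticleComplex(
        tuple(_strand_from_dict(s, "rna_strands")
              for s in d["rna_strands"]),
        tuple(d["arm_channels"]), gates, d["inhibitor_copies"])
    return particle, cond


def write_half_adder_spec(particle: NanoparticleComplex, path,
                          cond: Conditions | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(half_adder_to_dict(particle, cond), fh,
                       sort_keys=False)


def read_half_adder_spec(path) -> tuple:
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SpecFormatError(f"{path}: {exc}") from exc
    if not isinstance(d, dict):
        raise SpecFormatError(f"{path}: not a mapping")
    return half_adder_from_dict(d)
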