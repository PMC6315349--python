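"""Versioned nearest-neighbor parameter sets.

The energy model is a standard loop-decomposition nearest-neighbor model:
helical stacks carry sequence-dependent enthalpy/entropy, loops carry
size-dependent initiation penalties (treated as purely entropic, i.e. scaled
linearly in absolute temperature from their 37 °C values), and each
bimolecular association pays one initiation term.  Salt enters as an
entropic correction per stacked step using a monovalent-equivalent
concentration.

Three tables are shipped: Turner-style RNA/RNA (with G·U wobble), SantaLucia
style DNA/DNA, and Sugimoto-style RNA/DNA hybrid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

R_GAS = 1.98717e-3  # kcal/(mol*K)
T37 = 310.15        # K
JS_COEFF = 1.75 * R_GAS * T37  # Jacobson-Stockmayer loop extrapolation


class ParameterError(KeyError):
    """No nearest-neighbor entry for the requested step or polymer pair."""


def _mirror(key: str) -> str:
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


@dataclass(frozen=True)
class StackTable:
    """One chemistry's stack table plus initiation and terminal penalties."""

    source: str
    stacks: dict          # "XY/ZW" -> (dH kcal/mol, dS cal/mol/K)
    init: tuple           # (dH, dS) duplex/association initiation
    terminal_weak: tuple  # (dH, dS) penalty per weak (A·U/G·U/A·T) helix end
    wobble: bool

    def stack(self, key: str) -> tuple:
        try:
            return self.stacks[key]
        except KeyError:
            try:
                return self.stacks[_mirror(key)]
            except KeyError:
                raise ParameterError(f"no stack entry for {key!r} "
                                     f"in {self.source}") from None


def _load_table(name: str) -> StackTable:
    raw = json.loads(resources.files("aptalogic.data")
                     .joinpath(name).read_text())

    def to_hs(pair):
        dh, dg37 = pair
        return (dh, (dh - dg37) * 1000.0 / T37)

    return StackTable(
        source=raw["source"],
        stacks={k: to_hs(v) for k, v in raw["stacks"].items()},
        init=to_hs(raw["init"]),
        terminal_weak=to_hs(raw["terminal_weak"]),
        wobble=raw["wobble"],
    )


@lru_cache(maxsize=1)
def load_params() -> "NearestNeighborParams":
    loops = json.loads(resources.files("aptalogic.data")
                       .joinpath("loops.json").read_text())
    return NearestNeighborParams(
        rna=_load_table("nn_rna.json"),
        dna=_load_table("nn_dna.json"),
        hybrid=_load_table("nn_hybrid.json"),
        loops=loops,
    )


MIN_HAIRPIN = 3  # minimum unpaired nt in a hairpin loop (no nick)


@dataclass(frozen=True)
class NearestNeighborParams:
    """Complete parameter set: three stack tables plus loop penalties."""

    rna: StackTable
    dna: StackTable
    hybrid: StackTable
    loops: dict

    @property
    def version(self) -> str:
        return "aptalogic-1.0"

    def table_for(self, polymer_top: str, polymer_bottom: str) -> StackTable:
        if polymer_top == "RNA" and polymer_bottom == "RNA":
            return self.rna
        if polymer_top == "DNA" and polymer_bottom == "DNA":
            return self.dna
        return self.hybrid

    # -- loop penalties (dG37; callers scale entropically to T) ------------

    def _loop_dg37(self, kind: str, size: int) -> float:
        table = self.loops[kind]
        mx = self.loops["max_tabulated"][kind]
        if size <= mx:
            return table[str(size)]
        return table[str(mx)] + JS_COEFF * math.log(size / mx)

    def hairpin_dg37(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            raise ValueError(f"hairpin loop of size {size} < {MIN_HAIRPIN}")
        return self._loop_dg37("hairpin", size)

    def bulge_dg37(self, size: int) -> float:
        return self._loop_dg37("bulge", size)

    def internal_dg37(self, size: int) -> float:
        return self._loop_dg37("internal", max(size, 2))

    @property
    def multiloop_abc(self) -> tuple:
        return (self.loops["multiloop_a"], self.loops["multiloop_b"],
                self.loops["multiloop_c"])


def salt_entropy_per_step(sodium_equivalent: float) -> float:
    """Entropy adjustment (cal/mol/K) added to every stacked step."""
    return 0.368 * math.log(sodium_equivalent)


def loop_dg_at(dg37: float, kelvin: float) -> float:
    """Entropic extrapolation of a 37 °C loop penalty to temperature T."""
    return dg37 * kelvin / T37


def dg_at(dh: float, ds: float, kelvin: float) -> float:
    """dG (kcal/mol) from dH (kcal/mol) and dS (cal/mol/K)."""
    return dh - kelvin * ds / 1000.0
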