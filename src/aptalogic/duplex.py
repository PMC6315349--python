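"""Two-state duplex thermodynamics: hybridization energy and melting.

A duplex is scored by summing nearest-neighbor stacks over the aligned
complementary region, one association-initiation term, and a terminal
penalty per weak (A·U / G·U / A·T) helix end.  Salt enters as an entropic
correction per stacked step.  The melting temperature is the two-state
``Tm = ΔH / (ΔS + R ln(C_T/4))`` for non-self-complementary partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (NearestNeighborParams, R_GAS, load_params,
                     salt_entropy_per_step)
from .strands import Conditions, Strand, can_pair

WEAK_BASES = frozenset("AUT")


class DuplexError(ValueError):
    """Invalid duplex geometry (no overlap, too short, mismatch)."""


class TmDomainError(ValueError):
    """No finite two-state melting temperature for this duplex."""


@dataclass(frozen=True)
class DuplexEnergy:
    dH: float  # kcal/mol
    dS: float  # cal/mol/K (salt-corrected)
    dG: float  # kcal/mol at the requested temperature
    n_pairs: int


def _aligned_pairs(a: Strand, b: Strand, register: int) -> list[tuple[int, int]]:
    """Positions (i on a, j on b) facing each other: a[i] across b[-1-(i+register)]."""
    out = []
    for i in range(len(a)):
        j = len(b) - 1 - (i + register)
        if 0 <= j < len(b):
            out.append((i, j))
    return out


def best_register(a: Strand, b: Strand) -> int:
    """Register maximizing the number of complementary aligned positions
    (lowest register wins ties)."""
    best, best_n = 0, -1
    for reg in range(-(len(a) - 1), len(b)):
        n = sum(
            can_pair(a.sequence[i], b.sequence[j], a.polymer, b.polymer,
                     wobble=False)
            for i, j in _aligned_pairs(a, b, reg)
        )
        if n > best_n:
            best, best_n = reg, n
    return best


def duplex_energy(a: Strand, b: Strand, register: int | None = None,
                  cond: Conditions | None = None,
                  params: NearestNeighborParams | None = None) -> DuplexEnergy:
    """Hybridization ΔH/ΔS/ΔG of the a:b duplex at the given register.

    ``register`` aligns a against the reverse of b (``a[i]`` faces
    ``b[len(b)-1-(i+register)]``); ``None`` picks the register with maximal
    complementarity.  Wobble pairs are honored only where the parameter
    table allows them (RNA/RNA).
    """
    cond = cond or Conditions()
    params = params or load_params()
    table = params.table_for(a.polymer, b.polymer)
    if register is None:
        register = best_register(a, b)

    aligned = _aligned_pairs(a, b, register)
    paired = [
        (i, j) for i, j in aligned
        if can_pair(a.sequence[i], b.sequence[j], a.polymer, b.polymer,
                    wobble=table.wobble)
    ]
    if len(paired) < 2:
        raise DuplexError(
            f"{a.name}:{b.name} at register {register}: fewer than 2 "
            f"base pairs in the aligned region"
        )

    dH, dS = table.init
    salt_ds = salt_entropy_per_step(cond.sodium_equivalent)
    n_steps = 0
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        if i2 != i1 + 1 or j2 != j1 - 1:
            continue  # interrupted helix: unstacked, no loop term (two-state)
        key = (f"{a.sequence[i1]}{a.sequence[i2]}/"
               f"{b.sequence[j1]}{b.sequence[j2]}")
        h, s = table.stack(key)
        dH += h
        dS += s + salt_ds
        n_steps += 1
    if n_steps == 0:
        raise DuplexError(f"{a.name}:{b.name}: no stacked step (helix < 2 bp)")

    for i, j in (paired[0], paired[-1]):
        if a.sequence[i] in WEAK_BASES or b.sequence[j] in WEAK_BASES:
            h, s = table.terminal_weak
            dH += h
            dS += s

    dG = dH - cond.kelvin * dS / 1000.0
    return DuplexEnergy(dH, dS, dG, len(paired))


def melting_temperature(a: Strand, b: Strand, cond: Conditions,
                        register: int | None = None,
                        total_concentration: float | None = None,
                        params: NearestNeighborParams | None = None) -> float:
    """Two-state melting temperature (°C) of the a:b duplex.

    Total strand concentration C_T is read from ``cond.concentrations``
    (sum of both strands) unless passed explicitly.
    """
    if total_concentration is None:
        try:
            total_concentration = (cond.concentrations[a.name]
                                   + cond.concentrations[b.name])
        except KeyError as exc:
            raise ValueError(
                f"no concentration for strand {exc.args[0]!r}; supply "
                f"total_concentration or add it to Conditions"
            ) from None
    e = duplex_energy(a, b, register=register, cond=cond, params=params)
    denom = e.dS + 1000.0 * R_GAS * math.log(total_concentration / 4.0)
    if denom >= 0:
        raise TmDomainError(
            f"{a.name}:{b.name}: dS + R ln(C_T/4) = {denom:.2f} >= 0, "
            f"no finite two-state Tm"
        )
    return e.dH * 1000.0 / denom - 273.15
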