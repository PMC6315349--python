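"""Secondary structures over one or more strands, and their energies.

A structure is a set of base pairs over the 5'→3' concatenation of an
ordered strand list, with nicks recorded between strands.  Structures are
non-pseudoknotted (pairs nest) and score by loop decomposition:

* helical stacks — nearest-neighbor ΔH/ΔS with entropic salt correction,
* hairpin / bulge / internal loops — size-dependent initiation penalties,
* multiloops — affine ``a + b·branches + c·unpaired``,
* any loop interrupted by a nick — exterior-type, zero penalty,
* one association-initiation term per strand beyond the first,
* a terminal penalty per weak (A·U, G·U, A·T) helix end.

``structure_energy`` is the single scoring authority: the dynamic
program, the suboptimal enumerator and the exhaustive test oracle must all
agree with it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import (MIN_HAIRPIN, NearestNeighborParams, load_params,
                     loop_dg_at, salt_entropy_per_step)
from .strands import Conditions, can_pair
from .duplex import WEAK_BASES


class StructureError(ValueError):
    """Structure violates its invariants (crossing, clash, bad pair...)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairing over an ordered strand list, with optional energy."""

    strands: tuple
    pairs: frozenset          # {(i, j), i < j} global 0-based indices
    dG: float | None = None   # kcal/mol at the conditions it was folded at

    @staticmethod
    def open_chain(strands) -> "SecondaryStructure":
        return SecondaryStructure(tuple(strands), frozenset())

    @property
    def sequence(self) -> str:
        return "".join(s.sequence for s in self.strands)

    @property
    def n(self) -> int:
        return sum(len(s) for s in self.strands)

    @property
    def nick_boundaries(self) -> frozenset:
        """Boundaries b with a nick between global positions b and b+1."""
        out, pos = [], 0
        for s in self.strands[:-1]:
            pos += len(s)
            out.append(pos - 1)
        return frozenset(out)

    def polymer_of(self, i: int) -> str:
        for s in self.strands:
            if i < len(s):
                return s.polymer
            i -= len(s)
        raise IndexError(i)

    def strand_offsets(self) -> list[int]:
        offs, pos = [], 0
        for s in self.strands:
            offs.append(pos)
            pos += len(s)
        return offs

    def pair_map(self) -> dict:
        pm = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def with_dg(self, dg: float) -> "SecondaryStructure":
        return SecondaryStructure(self.strands, self.pairs, dg)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seq, n = self.sequence, self.n
        nicks = self.nick_boundaries
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise StructureError(f"position in pair ({i},{j}) is reused")
            seen.update((i, j))
            if not can_pair(seq[i], seq[j], self.polymer_of(i),
                            self.polymer_of(j)):
                raise StructureError(
                    f"({i},{j}) = {seq[i]}·{seq[j]} is not a legal pair")
            if j - i - 1 < MIN_HAIRPIN and not any(
                    i <= b < j for b in nicks):
                raise StructureError(
                    f"pair ({i},{j}) closes a loop shorter than "
                    f"{MIN_HAIRPIN} nt with no nick")
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i1, j1 = plist[a]
            for i2, j2 in plist[a + 1:]:
                if i2 >= j1:
                    break
                if not (j2 < j1):
                    raise StructureError(
                        f"pairs ({i1},{j1}) and ({i2},{j2}) cross "
                        f"(pseudoknot)")

    # -- dot-bracket -------------------------------------------------------

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        out, pos = [], 0
        for s in self.strands:
            out.append("".join(chars[pos:pos + len(s)]))
            pos += len(s)
        return "&".join(out)


def from_dot_bracket(strands, db: str,
                     dg: float | None = None) -> SecondaryStructure:
    """Parse ``(...)&(...)`` notation against an ordered strand list."""
    strands = tuple(strands)
    parts = db.split("&")
    if len(parts) != len(strands):
        raise StructureError(
            f"{len(parts)} dot-bracket segments for {len(strands)} strands")
    for part, s in zip(parts, strands):
        if len(part) != len(s):
            raise StructureError(
                f"segment length {len(part)} != strand {s.name} "
                f"length {len(s)}")
    flat = "".join(parts)
    stack, pairs = [], set()
    for i, c in enumerate(flat):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"bad dot-bracket character {c!r}")
    if stack:
        raise StructureError("unbalanced '(' remains")
    return SecondaryStructure(strands, frozenset(pairs), dg)


# -- loop decomposition and scoring ---------------------------------------

@dataclass
class Loop:
    closing: tuple | None     # closing pair, None for the exterior loop
    children: list = field(default_factory=list)
    unpaired: int = 0
    has_nick: bool = False
    kind: str = ""            # hairpin|stack|bulge|internal|multi|exterior


def decompose_loops(s: SecondaryStructure) -> list[Loop]:
    """All loops of the structure, classified (nick-aware)."""
    n = s.n
    nicks = s.nick_boundaries
    pm = s.pair_map()
    loops: list[Loop] = []

    def walk(i: int, j: int, closing) -> None:
        loop = Loop(closing)
        k = i
        while k <= j:
            if k in pm and pm[k] > k:
                loop.children.append((k, pm[k]))
                walk(k + 1, pm[k] - 1, (k, pm[k]))
                k = pm[k] + 1
            else:
                loop.unpaired += 1
                k += 1
        # loop-level boundaries: in [lo, hi] but not inside a child
        lo = (closing[0] if closing else 0)
        hi = (closing[1] - 1 if closing else n - 2)
        for b in nicks:
            if lo <= b <= hi and not any(ci <= b < cj
                                         for ci, cj in loop.children):
                loop.has_nick = True
        if closing is None:
            loop.kind = "exterior"
        elif loop.has_nick:
            loop.kind = "exterior"
        elif not loop.children:
            loop.kind = "hairpin"
        elif len(loop.children) == 1 and loop.unpaired == 0:
            loop.kind = "stack"
        elif len(loop.children) == 1:
            (ci, cj) = loop.children[0]
            s1, s2 = ci - closing[0] - 1, closing[1] - cj - 1
            loop.kind = "bulge" if min(s1, s2) == 0 else "internal"
        else:
            loop.kind = "multi"
        loops.append(loop)

    walk(0, n - 1, None)
    return loops


def structure_energy(s: SecondaryStructure, cond: Conditions | None = None,
                     params: NearestNeighborParams | None = None,
                     validate: bool = True) -> float:
    """Loop-decomposition free energy (kcal/mol) at ``cond.temperature``.

    The open chain scores exactly 0 for a single strand; each additional
    strand contributes one association-initiation term.
    """
    cond = cond or Conditions()
    params = params or load_params()
    if validate:
        s.validate()
    seq = s.sequence
    kelvin = cond.kelvin
    salt_ds = salt_entropy_per_step(cond.sodium_equivalent)
    ml_a, ml_b, ml_c = params.multiloop_abc

    energy = 0.0
    for a, b in zip(s.strands, s.strands[1:]):
        dh, ds = params.table_for(a.polymer, b.polymer).init
        energy += dh - kelvin * ds / 1000.0

    loops = decompose_loops(s)
    stack_inner: set = set()   # pairs whose enclosing-side loop is a stack
    stack_outer: set = set()   # pairs whose closed loop is a stack
    for loop in loops:
        if loop.kind == "stack":
            i, j = loop.closing
            k, l = loop.children[0]
            table = params.table_for(s.polymer_of(i), s.polymer_of(j))
            dh, ds = table.stack(f"{seq[i]}{seq[k]}/{seq[j]}{seq[l]}")
            energy += dh - kelvin * (ds + salt_ds) / 1000.0
            stack_inner.add((k, l))
            stack_outer.add((i, j))
        elif loop.kind == "hairpin":
            size = loop.closing[1] - loop.closing[0] - 1
            energy += loop_dg_at(params.hairpin_dg37(size), kelvin)
        elif loop.kind == "bulge":
            energy += loop_dg_at(params.bulge_dg37(loop.unpaired), kelvin)
        elif loop.kind == "internal":
            energy += loop_dg_at(params.internal_dg37(loop.unpaired), kelvin)
        elif loop.kind == "multi":
            dg37 = ml_a + ml_b * (1 + len(loop.children)) \
                + ml_c * loop.unpaired
            energy += loop_dg_at(dg37, kelvin)
        # exterior-type loops (incl. nick-interrupted): zero penalty

    for i, j in s.pairs:
        weak = seq[i] in WEAK_BASES or seq[j] in WEAK_BASES
        if not weak:
            continue
        table = params.table_for(s.polymer_of(i), s.polymer_of(j))
        dh, ds = table.terminal_weak
        term = dh - kelvin * ds / 1000.0
        if (i, j) not in stack_outer:   # inner helix end
            energy += term
        if (i, j) not in stack_inner:   # outer helix end
            energy += term
    return energy
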