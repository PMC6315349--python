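"""Sequence design for aptamer logic gates.

The designer turns a synthetic light-up aptamer core into complete gates
by construction, then verifies every candidate end-to-end through the
thermodynamic pipeline (fold → tube equilibrium → readout → truth table),
redrawing randomized segments until verification passes or the round
budget is exhausted — the executable form of a design-check-redesign loop.

Architectures
-------------
* Interfering gates (AND, OR): the 5'/3' extensions are reverse
  complements of the aptamer's outer stem plus a pocket half, so the
  no-input MFE sequesters stem keystones and pocket in two arm hairpins
  (OFF).  AND inputs strip one arm each, with an effective displacement
  Tm just above the operating temperature; OR inputs share the same gate
  RNA but are longer and additionally invade the far arm through a short
  bridge, so either input alone liberates the core.
* Non-interfering gates (NAND, NOR): the extensions are inert anchors
  that leave the core folded (ON).  Each NAND input carries, besides its
  anchor complement, a weak attacker domain against one flank of the
  core's inner stem; a single anchored attacker loses to the intact stem
  (gate stays ON) while both together collapse it (OFF only at 1-1).
  NOR inputs pair straight across an anchor and one outer-stem half,
  killing the ON fold on their own.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .duplex import duplex_energy
from .fold import fold_mfe
from .gates import (AptamerMotif, DFHBI_REPORTER, GateSpec, MG_REPORTER,
                    TRUTH, evaluate_truth_table)
from .params import NearestNeighborParams, R_GAS, load_params
from .strands import Conditions, Strand


class DesignFailure(RuntimeError):
    """Search exhausted without a verified design; carries the best try."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class DesignConstraints:
    """Architectural constants of the gate designs.

    ``and_tm_window`` and ``or_tm_margin`` constrain the *effective*
    displacement melting temperature of an input against its target arm
    (duplex formation net of the competing arm hairpin), in °C relative
    to ``operating_temp``.
    """

    operating_temp: float = 22.0
    input_len_range: tuple = (15, 27)
    and_tm_window: tuple = (0.0, 10.0)     # (low, high], °C above operating
    or_tm_margin: float = 15.0             # °C above operating, at least
    energy_gap_fraction: float = 0.20
    sticky_len: int = 17
    inhibitor_loop_len: int = 8
    max_redesign_rounds: int = 500
    rng_seed: int = 2018
    arm_gc_range: tuple = (0.40, 0.60)

    def __post_init__(self) -> None:
        if not (0.0 < self.energy_gap_fraction < 1.0):
            raise ValueError("energy_gap_fraction must be in (0, 1)")
        lo, hi = self.input_len_range
        if lo > hi or lo < 1:
            raise ValueError("empty input length range")
        if self.sticky_len > hi:
            raise ValueError("sticky_len must not exceed max input length")


# -- small sequence helpers ------------------------------------------------

def _rand_seq(rng, length, alphabet):
    return "".join(rng.choice(alphabet) for _ in range(length))


def _gc_fraction(seq: str) -> float:
    return sum(c in "GC" for c in seq) / len(seq) if seq else 0.0


def _rand_gc_seq(rng, length, gc_range, alphabet="ACGU"):
    for _ in range(200):
        s = _rand_seq(rng, length, alphabet)
        if gc_range[0] <= _gc_fraction(s) <= gc_range[1]:
            return s
    return s


def _rand_stem(rng, length):
    """G/C stem segment guaranteed to contain both letters."""
    while True:
        s = _rand_seq(rng, length, "GC")
        if "G" in s and "C" in s:
            return s


def _rc(seq: str, polymer: str) -> str:
    return Strand("_", "RNA" if "U" in seq or polymer == "RNA" else "DNA",
                  seq).reverse_complement(polymer=polymer).sequence


# -- aptamer core ----------------------------------------------------------

@dataclass(frozen=True)
class CoreDesign:
    """A synthetic light-up aptamer core: outer stem a:a', inner stem
    b:b', an unpaired dye pocket (p1, p2), and a terminal loop t.

    Layout (5'→3'): a p1 b t b' p2 a'.  This is a constructed stand-in
    with the architecture of an MG- or Broccoli-type switching aptamer,
    not a natural sequence.
    """

    a: str
    p1: str
    b: str
    t: str
    p2: str

    @property
    def b2(self) -> str:
        return _rc(self.b, "RNA")

    @property
    def a2(self) -> str:
        return _rc(self.a, "RNA")

    @property
    def sequence(self) -> str:
        return self.a + self.p1 + self.b + self.t + self.b2 + self.p2 + self.a2

    def spans(self, offset: int = 0) -> dict:
        out, pos = {}, offset
        for name, seg in [("a", self.a), ("p1", self.p1), ("b", self.b),
                          ("t", self.t), ("b2", self.b2), ("p2", self.p2),
                          ("a2", self.a2)]:
            out[name] = (pos, pos + len(seg))
            pos += len(seg)
        return out

    def stem_pairs(self, offset: int = 0) -> tuple:
        """((a-stem pairs...), (b-stem pairs...)) of the ON fold, global
        coordinates, outermost first."""
        sp = self.spans(offset)
        la, lb = len(self.a), len(self.b)
        a_pairs = tuple((sp["a"][0] + i, sp["a2"][1] - 1 - i)
                        for i in range(la))
        b_pairs = tuple((sp["b"][0] + k, sp["b2"][1] - 1 - k)
                        for k in range(lb))
        return a_pairs, b_pairs

    def motif(self, strand_name: str, offset: int = 0) -> AptamerMotif:
        """Keystone pairs (stem centers and deep stem pairs) plus the
        unpaired pocket define the ON state; helix-edge pairs are
        excluded so ordinary end fraying cannot flip classification."""
        sp = self.spans(offset)
        a_pairs, b_pairs = self.stem_pairs(offset)
        pairs = {a_pairs[len(a_pairs) // 2], a_pairs[-2],
                 b_pairs[1], b_pairs[len(b_pairs) // 2]}
        pocket = set(range(*sp["p1"])) | set(range(*sp["p2"]))
        return AptamerMotif(strand_name, (offset, sp["a2"][1] - 1),
                            frozenset(pairs), frozenset(pocket))

    def on_pairs(self, offset: int = 0) -> frozenset:
        return self.motif("_tmp_", offset).required_pairs


def make_core(rng: random.Random) -> CoreDesign:
    """Draw a random core whose ON fold is the designed stem-pocket-stem.

    Pocket and loop segments use A/C only (they can pair nothing among
    themselves); the a-stem has two weak outer positions so its helix
    ends melt before its keystones do.
    """
    while True:
        tail = _rand_seq(rng, 3, "GCGCU")
        if sum(c in "GC" for c in tail) >= 2:
            break
    a = "AU"[rng.random() < 0.5] + "U" + tail
    b = _rand_stem(rng, 5)
    p1 = "C" + _rand_seq(rng, 2, "AC") + "A"
    p2 = "A" + _rand_seq(rng, 2, "AC") + "C"
    t = "A" + _rand_seq(rng, 2, "AC") + "A"
    return CoreDesign(a=a, p1=p1, b=b, t=t, p2=p2)


# -- acceptance rule -------------------------------------------------------

@dataclass
class AcceptanceReport:
    accepted: bool
    dG_mfe: float
    mfe_matches_target: bool
    best_competitor_dG: float | None = None
    gap_fraction: float | None = None
    missing_pairs: tuple = ()
    blocked_positions: tuple = ()


def accept_sequence(strands, target_pairs, target_unpaired,
                    cond: Conditions | None = None,
                    constraints: DesignConstraints | None = None,
                    params: NearestNeighborParams | None = None):
    """Accept a sequence iff its MFE realizes the target conformation and
    no conformation-breaking structure comes within the energy gap.

    ``target_pairs`` are the conformation's keystone pairs (global
    coordinates) that must be present, ``target_unpaired`` positions that
    must stay single-stranded, in the MFE.  The best competing structure
    is the minimum over constrained refolds that forbid one keystone; it
    must lie at least ``energy_gap_fraction · |dG_mfe|`` above the MFE.
    """
    cond = cond or Conditions()
    constraints = constraints or DesignConstraints()
    params = params or load_params()
    target_pairs = frozenset((min(i, j), max(i, j)) for i, j in target_pairs)
    target_unpaired = frozenset(target_unpaired)

    mfe = fold_mfe(strands, cond, params)
    pm = mfe.pair_map()
    missing = tuple(sorted(p for p in target_pairs if pm.get(p[0]) != p[1]))
    blocked = tuple(sorted(q for q in target_unpaired if q in pm))
    matches = not missing and not blocked

    if not target_pairs:
        # open-chain-like target: accept iff nothing beats the open chain
        accepted = matches and mfe.dG >= -1e-9
        return accepted, AcceptanceReport(accepted, mfe.dG, matches,
                                          missing_pairs=missing,
                                          blocked_positions=blocked)
    if not matches:
        return False, AcceptanceReport(False, mfe.dG, False,
                                       missing_pairs=missing,
                                       blocked_positions=blocked)

    best_bad = None
    for p in sorted(target_pairs):
        alt = fold_mfe(strands, cond, params, forbid_pairs=[p])
        if best_bad is None or alt.dG < best_bad:
            best_bad = alt.dG
    gap = (best_bad - mfe.dG) / abs(mfe.dG) if mfe.dG < -1e-9 else float("inf")
    accepted = gap >= constraints.energy_gap_fraction - 1e-12
    return accepted, AcceptanceReport(accepted, mfe.dG, True, best_bad, gap)


# -- effective displacement melting temperature ---------------------------

def effective_tm(input_strand: Strand, domains, cond: Conditions,
                 total_concentration: float,
                 params: NearestNeighborParams | None = None) -> float:
    """Two-state Tm of input binding net of the competing arm hairpin(s).

    ``domains`` is a list of ``(site_rna, hairpin_top, hairpin_bottom)``
    tuples: the reaction is input + closed hairpin(s) ⇌ bound input +
    opened arm(s); ΔH/ΔS sum the input:site hybrid duplexes minus the
    hairpin helices (stacks and terminal penalties only — hairpins are
    intramolecular, so their association initiations are removed), with
    one bimolecular association counted in total.
    """
    params = params or load_params()
    ih, is_ = params.rna.init
    dh = ds = 0.0
    for k, (site_rna, hp_top, hp_bottom) in enumerate(domains):
        site = Strand("_site", "RNA", site_rna)
        d1 = duplex_energy(site, input_strand, cond=cond, params=params)
        dh += d1.dH
        ds += d1.dS
        if k > 0:   # only one association event for the whole input
            dh -= ih
            ds -= is_
        if hp_top is not None:
            top = Strand("_t", "RNA", hp_top)
            bottom = Strand("_b", "RNA", hp_bottom)
            d2 = duplex_energy(top, bottom, cond=cond, params=params)
            dh -= d2.dH - ih
            ds -= d2.dS - is_
    denom = ds + 1000.0 * R_GAS * math.log(total_concentration / 4.0)
    if denom >= 0 or dh >= 0:
        return float("-inf")  # binding never reaches half-completion
    return dh * 1000.0 / denom - 273.15


# -- interfering gates (AND / OR) -----------------------------------------

@dataclass(frozen=True)
class InterferingGatePair:
    """AND and OR gates sharing one interfering-end gate RNA."""

    gate_strand: Strand
    core: CoreDesign
    core_offset: int
    segments: dict              # name -> (start, end) on the gate strand
    and_gate: GateSpec
    or_gate: GateSpec
    report: dict


def _assemble(parts, name, polymer="RNA"):
    segs, pos, seq = {}, 0, ""
    for nm, sg in parts:
        segs[nm] = (pos, pos + len(sg))
        pos += len(sg)
        seq += sg
    return Strand(name, polymer, seq), segs


def _seg(strand: Strand, segs: dict, *names: str) -> str:
    return "".join(strand.sequence[slice(*segs[nm])] for nm in names)


def design_interfering_gate(core: CoreDesign,
                            constraints: DesignConstraints | None = None,
                            cond: Conditions | None = None,
                            params: NearestNeighborParams | None = None,
                            rng: random.Random | None = None,
                            name_prefix: str = "ANDOR",
                            verbose: bool = False) -> InterferingGatePair:
    """Design the shared interfering gate RNA plus AND and OR inputs."""
    constraints = constraints or DesignConstraints()
    cond = cond or Conditions()
    params = params or load_params()
    rng = rng or random.Random(constraints.rng_seed)
    best = None

    # Arms: X sequesters (a p1), Y sequesters (p2 a')
    x_site = core.a + core.p1
    y_site = core.p2 + core.a2
    x = _rc(x_site, "RNA")
    y = _rc(y_site, "RNA")

    ct = 2e-6 + 1e-6
    t_lo = constraints.operating_temp + constraints.and_tm_window[0]
    t_hi = constraints.operating_temp + constraints.and_tm_window[1]

    def tuned_toehold(full, site, hp_top, hp_bottom, tail):
        """Longest toehold slice whose displacement Tm is in the window."""
        for length in range(6, len(full) + 1):
            cand = full[-length:] if tail else full[:length]
            seq = (site + cand) if tail else (cand + site)
            inp = Strand("_cand", "DNA", _rc(seq, "DNA"))
            tm = effective_tm(inp, [(seq, hp_top, hp_bottom)], cond, ct,
                              params)
            if t_lo < tm <= t_hi:
                return cand, tm
        return None, None

    for round_no in range(constraints.max_redesign_rounds):
        # strong G/C-block toeholds: the AND displacement must overcome
        # both the arm hairpin and the bimolecular association entropy
        f1_full = "".join(rng.choice(("GG", "CC", "GC", "CG"))
                          for _ in range(5))
        f2_full = "".join(rng.choice(("GG", "CC", "GC", "CG"))
                          for _ in range(5))
        f1, tm_a = tuned_toehold(f1_full, x, x, x_site, tail=False)
        f2, tm_b = tuned_toehold(f2_full, y, y_site, y, tail=True)
        if f1 is None or f2 is None:
            best = best or ("no toehold length lands in the AND Tm window",
                            None)
            continue
        s1 = _rand_seq(rng, 4, "AC")
        s2 = _rand_seq(rng, 4, "AC")
        gate, segs = _assemble(
            [("f1", f1), ("X", x), ("s1", s1), ("core", core.sequence),
             ("s2", s2), ("Y", y), ("f2", f2)], f"{name_prefix}_gate")
        core_off = segs["core"][0]
        motif = core.motif(gate.name, core_off)

        # OFF-state target keystones: arm pairs holding the core keystones
        x0, x1 = segs["X"]
        y0, y1 = segs["Y"]
        # arm partner of each sequestered core position (antiparallel)
        x_tgt = {t: x1 - 1 - (t - core_off)
                 for t in range(core_off, core_off + len(x_site))}
        y_site0 = segs["s2"][0] - len(y_site)
        y_tgt = {t: y0 + (y_site0 + len(y_site) - 1 - t)
                 for t in range(y_site0, y_site0 + len(y_site))}
        a_keys, b_keys = core.stem_pairs(core_off)
        tgt = set()
        for ai, aj in (a_keys[len(a_keys) // 2], a_keys[-2]):
            tgt.add((x_tgt[ai], ai))
            tgt.add((aj, y_tgt[aj]))
        # The OFF-state check demands an exact MFE match on the arm
        # keystones.  The full relative-gap rule is not applied here: the
        # best competitor of an interfering OFF state is the partial ON
        # refold, and keeping that within reach of the weakly-bound AND
        # inputs is precisely what makes the gate switchable.  The gap
        # rule applies to the core in isolation (the design
        # precondition); the measured gate-level gap is reported.
        ok, rep = accept_sequence([gate], tgt, (), cond, constraints, params)
        if not rep.mfe_matches_target:
            best = best or ("gate OFF-state MFE mismatch", rep)
            continue

        in_a = Strand(f"{name_prefix}_AND_inA", "DNA",
                      _rc(_seg(gate, segs, "f1", "X"), "DNA"))
        in_b = Strand(f"{name_prefix}_AND_inB", "DNA",
                      _rc(_seg(gate, segs, "Y", "f2"), "DNA"))
        # OR inputs: two arm-stripping domains each — one for the far arm
        # (with a slice of its terminal toehold) and one for the near arm
        # (with the adjacent spacer as toehold) — so a single input
        # neutralizes both interfering ends at once
        or_site_a2 = _seg(gate, segs, "X", "s1")
        or_site_a1 = _seg(gate, segs, "Y") + f2[:4]
        or_site_b1 = _seg(gate, segs, "s2", "Y")
        or_site_b2 = f1[-4:] + _seg(gate, segs, "X")
        or_a = Strand(f"{name_prefix}_OR_inA", "DNA",
                      _rc(or_site_a1, "DNA") + _rc(or_site_a2, "DNA"))
        or_b = Strand(f"{name_prefix}_OR_inB", "DNA",
                      _rc(or_site_b1, "DNA") + _rc(or_site_b2, "DNA"))

        lo, hi = constraints.input_len_range
        if not all(lo <= len(s) <= hi for s in (in_a, in_b, or_a, or_b)):
            best = best or ("input length out of range", None)
            continue

        # OR inputs are longer and bind with a much higher plain duplex
        # Tm (two-state Tm of the whole input against its sites)
        tm_or_a = effective_tm(
            or_a, [(or_site_a2, None, None), (or_site_a1, None, None)],
            cond, ct, params)
        tm_or_b = effective_tm(
            or_b, [(or_site_b1, None, None), (or_site_b2, None, None)],
            cond, ct, params)
        t_or = constraints.operating_temp + constraints.or_tm_margin
        if not (tm_or_a >= t_or and tm_or_b >= t_or):
            best = best or (f"OR Tm below margin: {tm_or_a:.1f}/"
                            f"{tm_or_b:.1f}", None)
            continue

        and_gate = GateSpec("AND", (gate,), motif, in_a, in_b, MG_REPORTER)
        or_gate = GateSpec("OR", (gate,), motif, or_a, or_b, MG_REPORTER)
        tt_and = evaluate_truth_table(and_gate, cond, params)
        if tt_and.bits != TRUTH["AND"]:
            best = ("AND truth table failed", tt_and)
            if verbose:
                print(f"round {round_no}: AND bits {tt_and.bits} "
                      f"{[round(p, 1) for p in tt_and.normalized_percent]}")
            continue
        tt_or = evaluate_truth_table(or_gate, cond, params)
        if tt_or.bits != TRUTH["OR"]:
            best = ("OR truth table failed", tt_or)
            if verbose:
                print(f"round {round_no}: OR bits {tt_or.bits} "
                      f"{[round(p, 1) for p in tt_or.normalized_percent]}")
            continue
        report = {"off_state": rep, "tm_and": (tm_a, tm_b),
                  "tm_or": (tm_or_a, tm_or_b),
                  "truth": {"AND": tt_and, "OR": tt_or}}
        return InterferingGatePair(gate, core, core_off, segs,
                                   and_gate, or_gate, report)
    raise DesignFailure(
        f"no interfering design in {constraints.max_redesign_rounds} rounds "
        f"(last: {best[0] if best else 'n/a'})", best)


# -- non-interfering gates (NAND / NOR) -----------------------------------

@dataclass(frozen=True)
class NonInterferingGatePair:
    gate_strand: Strand
    core: CoreDesign
    core_offset: int
    segments: dict
    nand_gate: GateSpec
    nor_gate: GateSpec
    report: dict


def design_noninterfering_gate(core: CoreDesign,
                               constraints: DesignConstraints | None = None,
                               cond: Conditions | None = None,
                               params: NearestNeighborParams | None = None,
                               rng: random.Random | None = None,
                               name_prefix: str = "NANDNOR",
                               verbose: bool = False
                               ) -> NonInterferingGatePair:
    """Design the shared non-interfering gate RNA plus NAND/NOR inputs."""
    constraints = constraints or DesignConstraints()
    cond = cond or Conditions()
    params = params or load_params()
    rng = rng or random.Random(constraints.rng_seed + 1)
    best = None

    for round_no in range(constraints.max_redesign_rounds):
        e1 = _rand_gc_seq(rng, 11, constraints.arm_gc_range)
        e2 = _rand_gc_seq(rng, 11, constraints.arm_gc_range)
        s1 = _rand_seq(rng, 4, "AC")
        s2 = _rand_seq(rng, 4, "AC")
        gate, segs = _assemble(
            [("e1", e1), ("s1", s1), ("core", core.sequence),
             ("s2", s2), ("e2", e2)], f"{name_prefix}_gate")
        core_off = segs["core"][0]
        motif = core.motif(gate.name, core_off)
        sp = core.spans(core_off)

        # ON-state target: the non-interfering ends must leave the core
        # keystones folded and the pocket open
        ok, rep = accept_sequence([gate], motif.required_pairs,
                                  motif.pocket_positions, cond,
                                  constraints, params)
        if not rep.mfe_matches_target:
            best = best or ("gate ON-state MFE mismatch", rep)
            continue

        # NAND inputs: anchor complement extended 3 nt into the outer stem
        # (A over a[0:3] from the 5' side, B over the matching a'
        # positions from the 3' side).  A single extension loses the
        # local competition with the intact stem; both extensions share
        # the stem-opening cost and win only together.
        reach = len(core.a) - 1
        nand_a = Strand(f"{name_prefix}_NAND_inA", "DNA",
                        _rc(_seg(gate, segs, "e1", "s1")
                            + core.a[:reach], "DNA"))
        nand_b = Strand(f"{name_prefix}_NAND_inB", "DNA",
                        _rc(core.a2[len(core.a) - reach:]
                            + _seg(gate, segs, "s2", "e2"), "DNA"))
        # NOR inputs: the same anchored invasion but spanning the whole
        # outer stem plus a pocket overhang, which tips the global balance
        # to a complete single-input kill
        nor_a = Strand(f"{name_prefix}_NOR_inA", "DNA",
                       _rc(_seg(gate, segs, "e1", "s1") + core.a
                           + core.p1, "DNA"))
        nor_b = Strand(f"{name_prefix}_NOR_inB", "DNA",
                       _rc(core.p2 + core.a2
                           + _seg(gate, segs, "s2", "e2"), "DNA"))
        lo, hi = constraints.input_len_range
        if not all(lo <= len(s) <= hi
                   for s in (nand_a, nand_b, nor_a, nor_b)):
            best = best or ("input length out of range", None)
            continue

        nand = GateSpec("NAND", (gate,), motif, nand_a, nand_b,
                        MG_REPORTER, input_multiplier=2.0)
        nor = GateSpec("NOR", (gate,), motif, nor_a, nor_b, MG_REPORTER)
        tt_nand = evaluate_truth_table(nand, cond, params)
        if tt_nand.bits != TRUTH["NAND"]:
            best = ("NAND truth table failed", tt_nand)
            if verbose:
                print(f"round {round_no}: NAND bits {tt_nand.bits} "
                      f"{[round(p, 1) for p in tt_nand.normalized_percent]}")
            continue
        tt_nor = evaluate_truth_table(nor, cond, params)
        if tt_nor.bits != TRUTH["NOR"]:
            best = ("NOR truth table failed", tt_nor)
            if verbose:
                print(f"round {round_no}: NOR bits {tt_nor.bits} "
                      f"{[round(p, 1) for p in tt_nor.normalized_percent]}")
            continue
        report = {"on_state": rep, "truth": {"NAND": tt_nand, "NOR": tt_nor}}
        return NonInterferingGatePair(gate, core, core_off, segs, nand, nor,
                                      report)
    raise DesignFailure(
        f"no non-interfering design in {constraints.max_redesign_rounds} "
        f"rounds (last: {best[0] if best else 'n/a'})", best)


# -- inhibitor gates (XOR and displacement-AND, shared inputs) ------------

@dataclass(frozen=True)
class InhibitorGateSet:
    """XOR (DFHBI channel) and displacement-AND (MG channel) gates driven
    by one shared input pair carrying mutually complementary sticky ends."""

    xor_arm: Strand            # Broccoli-type aptamer arm (RNA)
    and_arm: Strand            # MG-type aptamer arm (RNA)
    xor_inhibitor: Strand      # XOR_DNA
    and_inhibitor: Strand      # AND_DNA
    input_a: Strand
    input_b: Strand
    xor_gate: GateSpec
    and_gate: GateSpec
    xor_core: "CoreDesign"
    and_core: "CoreDesign"
    report: dict


def sticky_overlap(a: Strand, b: Strand) -> int:
    """Longest Watson-Crick complementary run between a's 5' terminus and
    b's 3' terminus (the half adder's input-pairing handshake)."""
    n = 0
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    while n < min(len(a), len(b)) and \
            b.sequence[len(b) - 1 - n] == comp[a.sequence[n]]:
        n += 1
    return n


def design_inhibitor_pair(xor_core: CoreDesign, and_core: CoreDesign,
                          constraints: DesignConstraints | None = None,
                          cond: Conditions | None = None,
                          params: NearestNeighborParams | None = None,
                          rng: random.Random | None = None,
                          name_prefix: str = "HA",
                          verbose: bool = False) -> InhibitorGateSet:
    """Design the shared inputs plus XOR_DNA / AND_DNA inhibitors.

    The XOR inhibitor holds the Broccoli-type arm OFF through three weak
    duplex blocks separated by two 8-nt single-stranded loops
    complementary to the inputs; either input invades through its loop
    (plus a block overlap) and strips the inhibitor.  The inputs carry
    17 mutually complementary sticky nucleotides (5' of A, 3' of B), so
    at 1-1 they preferentially pair with each other and leave the XOR
    inhibitor in place.  The AND inhibitor's sticky ends copy the inputs'
    inhibitor-binding toeholds; only both inputs together zipper it into
    a three-stranded complex (input A : inhibitor : input B closed by the
    A:B sticky duplex) that frees the MG-type arm.
    """
    constraints = constraints or DesignConstraints()
    cond = cond or Conditions()
    params = params or load_params()
    rng = rng or random.Random(constraints.rng_seed + 2)
    loop_len = constraints.inhibitor_loop_len
    sticky_len = constraints.sticky_len
    best = None

    for round_no in range(constraints.max_redesign_rounds):
        g1 = _rand_gc_seq(rng, 6, constraints.arm_gc_range)
        g2 = _rand_gc_seq(rng, 6, constraints.arm_gc_range)
        g3 = _rand_gc_seq(rng, 6, constraints.arm_gc_range)
        g4 = _rand_gc_seq(rng, 6, constraints.arm_gc_range)
        xor_arm, xsegs = _assemble(
            [("g1", g1), ("core", xor_core.sequence), ("g2", g2)],
            f"{name_prefix}_XOR_arm")
        and_arm, msegs = _assemble(
            [("g1", g3), ("core", and_core.sequence), ("g2", g4)],
            f"{name_prefix}_AND_arm")
        xc, mc = xor_core, and_core

        # XOR inhibitor: three duplex blocks over (a' + flank), (p1 + b
        # start) and (flank + a).  Their combined hold must beat the
        # folded arm by only a few kcal/mol, so that the loop toehold
        # plus block overlap of a single input can strip the inhibitor;
        # the flank-anchoring extents are part of the search.
        ext1 = rng.randint(2, 5)
        ext3 = rng.randint(2, 5)
        # deep block overlap: the two input toeholds then conflict over
        # the central block, so they cannot jointly sequester the
        # inhibitor at 1-1 (the sticky A:B duplex wins instead)
        overlap = rng.randint(4, 5)
        d1 = _rc(xc.a2 + g2[:ext1], "DNA")
        d2 = _rc(xc.p1 + xc.b[:2], "DNA")
        d3 = _rc(g1[len(g1) - ext3:] + xc.a, "DNA")
        # near-complementary loops: once the inputs pair via their sticky
        # ends, the A:B duplex zips on through both loop complements
        # (burying the toeholds exactly when both inputs are present); a
        # single mismatch at the sticky boundary keeps the terminal
        # complementary run at exactly sticky_len
        l2 = _rc(_rand_seq(rng, loop_len, "ACGT"), "DNA")
        l1 = l2[-1] + _rc(l2, "DNA")[1:]
        ix, ixsegs = _assemble(
            [("d1", d1), ("l1", l1), ("d2", d2), ("l2", l2), ("d3", d3)],
            f"{name_prefix}_XOR_DNA", polymer="DNA")

        # Shared inputs: sticky 17 + inhibitor toehold (loop + block
        # slice).  Input A attacks the 3'-side loop and B the 5'-side
        # loop: with this orientation the sticky A:B duplex and the two
        # toehold bindings cannot coexist on the XOR inhibitor without a
        # pseudoknot, so paired inputs leave it in place at 1-1.
        toe_a = _rc(ix.sequence[ixsegs["d2"][1] - overlap:ixsegs["l2"][1]],
                    "DNA")
        toe_b = _rc(ix.sequence[ixsegs["l1"][0]:ixsegs["d2"][0] + overlap],
                    "DNA")
        sticky = _rand_gc_seq(rng, sticky_len, (0.6, 0.8), alphabet="ACGT")
        in_a = Strand(f"{name_prefix}_inA", "DNA", sticky + toe_a)
        in_b = Strand(f"{name_prefix}_inB", "DNA",
                      toe_b + _rc(sticky, "DNA"))
        if sticky_overlap(in_a, in_b) != sticky_len:
            best = best or ("sticky handshake length off", None)
            continue

        # AND inhibitor: sticky ends copy the inputs' inhibitor toeholds,
        # middle block holds the MG arm (pocket half + outer stem)
        m_ext = rng.randint(2, 5)
        m_block = _rc(mc.p2 + mc.a2 + and_arm.sequence[
            msegs["g2"][0]:msegs["g2"][0] + m_ext], "DNA")
        ia, iasegs = _assemble(
            [("e1", _rc(toe_a, "DNA")), ("m", m_block),
             ("e2", _rc(toe_b, "DNA"))],
            f"{name_prefix}_AND_DNA", polymer="DNA")

        xor_motif = xc.motif(xor_arm.name, xsegs["core"][0])
        and_motif = mc.motif(and_arm.name, msegs["core"][0])

        # cheap structural pre-screens before the full tube evaluation
        from .gates import is_on_state
        if not is_on_state(fold_mfe([xor_arm], cond, params), xor_motif):
            best = best or ("free XOR arm does not fold ON", None)
            continue
        if not is_on_state(fold_mfe([and_arm], cond, params), and_motif):
            best = best or ("free AND arm does not fold ON", None)
            continue
        if is_on_state(fold_mfe([xor_arm, ix], cond, params), xor_motif):
            best = best or ("XOR inhibitor fails to hold the arm OFF",
                            None)
            continue
        if is_on_state(fold_mfe([and_arm, ia], cond, params), and_motif):
            best = best or ("AND inhibitor fails to hold the arm OFF",
                            None)
            continue

        xor_gate = GateSpec(
            "XOR", (xor_arm,), xor_motif, in_a, in_b, DFHBI_REPORTER,
            inhibitor=ix, gate_concentration=2e-6,
            input_concentration=5e-6, inhibitor_ratio=1.0)
        and_gate = GateSpec(
            "AND", (and_arm,), and_motif, in_a, in_b, MG_REPORTER,
            inhibitor=ia, gate_concentration=2e-6,
            input_concentration=5e-6, inhibitor_ratio=1.0)

        tt_xor = evaluate_truth_table(xor_gate, cond, params)
        if tt_xor.bits != TRUTH["XOR"]:
            best = ("XOR truth table failed", tt_xor)
            if verbose:
                print(f"round {round_no}: XOR bits {tt_xor.bits} "
                      f"{[round(p, 1) for p in tt_xor.normalized_percent]}")
            continue
        tt_and = evaluate_truth_table(and_gate, cond, params)
        if tt_and.bits != TRUTH["AND"]:
            best = ("displacement-AND truth table failed", tt_and)
            if verbose:
                print(f"round {round_no}: AND bits {tt_and.bits} "
                      f"{[round(p, 1) for p in tt_and.normalized_percent]}")
            continue
        report = {"truth": {"XOR": tt_xor, "AND": tt_and},
                  "segments": ixsegs, "and_segments": iasegs,
                  "overlap": overlap}
        return InhibitorGateSet(xor_arm, and_arm, ix, ia, in_a, in_b,
                                xor_gate, and_gate, xor_core, and_core,
                                report)
    raise DesignFailure(
        f"no inhibitor design in {constraints.max_redesign_rounds} rounds "
        f"(last: {best[0] if best else 'n/a'})", best)
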