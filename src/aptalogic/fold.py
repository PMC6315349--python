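"""Minimum-free-energy folding over nicked concatenations of ≤3 strands.

A Zuker-style dynamic program over the loop-decomposition model of
:mod:`aptalogic.structure`.  Strand nicks are handled exactly: a loop that
contains a nick at loop level is exterior-type (zero penalty, no hairpin
minimum), stacking never spans a nick (no coaxial stacking), and each extra
strand pays one association-initiation term.  The DP energy is provably the
minimum of ``structure_energy`` over all legal structures — the test suite
enforces this against an exhaustive enumeration oracle.

Recursion tables (all ΔG at temperature T, kcal/mol):

* ``V[i,j]``   — best energy of a structure closed by pair (i,j),
  excluding the pair's outer-side terminal penalty.
* ``M[i,j]``   — multiloop interior with ≥1 branch.
* ``M2[i,j]``  — multiloop interior with ≥2 branches.
* ``WX[i,j]``  — exterior-style region: unpaired free, each branch pays
  its outer terminal penalty, no loop penalty.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import NearestNeighborParams, load_params, loop_dg_at, \
    salt_entropy_per_step
from .strands import Conditions, Strand, can_pair
from .structure import SecondaryStructure
from .duplex import WEAK_BASES

INF = 1e9
MAXLOOP = 30          # max unpaired nt in an internal/bulge loop
DEFAULT_MAX_LEN = 400
DEFAULT_MAX_STRANDS = 3
_EPS = 1e-7


class FoldResourceError(ValueError):
    """Input exceeds the configured folding caps."""


def _precompute(strands, cond, params, forbid_pairs=(), forbid_positions=()):
    seq = "".join(s.sequence for s in strands)
    n = len(seq)
    polymers = []
    for s in strands:
        polymers.extend([s.polymer] * len(s))
    kelvin = cond.kelvin
    salt_ds = salt_entropy_per_step(cond.sodium_equivalent)

    nickb = np.zeros(n, dtype=np.bool_)
    pos = 0
    for s in strands[:-1]:
        pos += len(s)
        nickb[pos - 1] = True

    forbid_pairs = {(min(i, j), max(i, j)) for i, j in forbid_pairs}
    forbid_positions = set(forbid_positions)
    allowed = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in forbid_pairs or i in forbid_positions \
                    or j in forbid_positions:
                continue
            allowed[i, j] = can_pair(seq[i], seq[j], polymers[i],
                                     polymers[j])
    # wobble only where the table allows it (RNA/RNA); can_pair already
    # restricts wobble to RNA/RNA, so `allowed` is final.

    termE = np.zeros((n, n))
    stackE = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + 1, n):
            if not allowed[i, j]:
                continue
            table = params.table_for(polymers[i], polymers[j])
            if seq[i] in WEAK_BASES or seq[j] in WEAK_BASES:
                dh, ds = table.terminal_weak
                termE[i, j] = dh - kelvin * ds / 1000.0
            if i + 1 < j - 1 and allowed[i + 1, j - 1] \
                    and not nickb[i] and not nickb[j - 1]:
                dh, ds = table.stack(
                    f"{seq[i]}{seq[i + 1]}/{seq[j]}{seq[j - 1]}")
                stackE[i, j] = dh - kelvin * (ds + salt_ds) / 1000.0

    hp = np.full(n + 1, INF)
    bu = np.full(n + 1, INF)
    il = np.full(n + 1, INF)
    for size in range(3, n + 1):
        hp[size] = loop_dg_at(params.hairpin_dg37(size), kelvin)
    for size in range(1, n + 1):
        bu[size] = loop_dg_at(params.bulge_dg37(size), kelvin)
    for size in range(2, n + 1):
        il[size] = loop_dg_at(params.internal_dg37(size), kelvin)
    ml_a, ml_b, ml_c = (loop_dg_at(x, kelvin) for x in params.multiloop_abc)

    assoc = 0.0
    for a, b in zip(strands, strands[1:]):
        dh, ds = params.table_for(a.polymer, b.polymer).init
        assoc += dh - kelvin * ds / 1000.0
    return (seq, np.asarray(allowed), stackE, termE, nickb, hp, bu, il,
            ml_a, ml_b, ml_c, assoc)


@njit(cache=True)
def _fill(n, allowed, stackE, termE, nickb, hp, bu, il,
          ml_a, ml_b, ml_c, maxloop):
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M2 = np.full((n, n), INF)
    WX = np.zeros((n, n))

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span

            # ---- V ----
            if allowed[i, j]:
                best = INF
                # hairpin (no nick inside the loop)
                nickfree = True
                for b in range(i, j):
                    if nickb[b]:
                        nickfree = False
                        break
                if nickfree and j - i - 1 >= 3:
                    e = hp[j - i - 1] + termE[i, j]
                    if e < best:
                        best = e
                # nick-interrupted (exterior-type) loop
                if not nickfree:
                    for b in range(i, j):
                        if not nickb[b]:
                            continue
                        e = termE[i, j]
                        if b >= i + 1:
                            e += WX[i + 1, b]
                        if b + 1 <= j - 1:
                            e += WX[b + 1, j - 1]
                        if e < best:
                            best = e
                # stack
                if stackE[i, j] < INF and V[i + 1, j - 1] < INF:
                    e = stackE[i, j] + V[i + 1, j - 1]
                    if e < best:
                        best = e
                # internal / bulge loops (boundaries i and j-1 are at loop
                # level on both sides, so a nick there forbids the case)
                if not nickb[i] and not nickb[j - 1]:
                    kmax = min(i + 1 + maxloop, j - 2)
                    for k in range(i + 1, kmax + 1):
                        s1 = k - i - 1
                        if k - 1 > i and nickb[k - 1]:
                            break  # nick entered the 5' loop span
                        lmin = max(k + 1, j - 1 - (maxloop - s1))
                        for l in range(j - 1, lmin - 1, -1):
                            s2 = j - l - 1
                            if s1 + s2 == 0:
                                continue
                            if l < j - 1 and nickb[l]:
                                break
                            if not allowed[k, l] or V[k, l] >= INF:
                                continue
                            if s1 == 0 or s2 == 0:
                                lp = bu[s1 + s2]
                            else:
                                lp = il[s1 + s2]
                            e = lp + termE[i, j] + termE[k, l] + V[k, l]
                            if e < best:
                                best = e
                # multiloop
                if not nickb[i] and not nickb[j - 1] and j - i >= 2:
                    if M2[i + 1, j - 1] < INF:
                        e = ml_a + ml_b + termE[i, j] + M2[i + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best

            # ---- M ----
            best = INF
            if allowed[i, j] and V[i, j] < INF:
                e = V[i, j] + termE[i, j] + ml_b
                if e < best:
                    best = e
            if not nickb[j - 1] and M[i, j - 1] < INF:
                e = M[i, j - 1] + ml_c
                if e < best:
                    best = e
            if not nickb[i] and M[i + 1, j] < INF:
                e = M[i + 1, j] + ml_c
                if e < best:
                    best = e
            for k in range(i + 1, j):
                if nickb[k - 1]:
                    continue
                if M[i, k - 1] < INF and allowed[k, j] and V[k, j] < INF:
                    e = M[i, k - 1] + V[k, j] + termE[k, j] + ml_b
                    if e < best:
                        best = e
            M[i, j] = best

            # ---- M2 ----
            best = INF
            if not nickb[j - 1] and M2[i, j - 1] < INF:
                e = M2[i, j - 1] + ml_c
                if e < best:
                    best = e
            for k in range(i + 1, j):
                if nickb[k - 1]:
                    continue
                if M[i, k - 1] < INF and allowed[k, j] and V[k, j] < INF:
                    e = M[i, k - 1] + V[k, j] + termE[k, j] + ml_b
                    if e < best:
                        best = e
            M2[i, j] = best

            # ---- WX ----
            best = WX[i, j - 1]
            for k in range(i, j):
                if allowed[k, j] and V[k, j] < INF:
                    e = V[k, j] + termE[k, j]
                    if k > i:
                        e += WX[i, k - 1]
                    if e < best:
                        best = e
            if allowed[i, j] and V[i, j] < INF:
                e = V[i, j] + termE[i, j]
                if e < best:
                    best = e
            WX[i, j] = best
    return V, M, M2, WX


def _traceback(n, tabs, pre):
    (V, M, M2, WX) = tabs
    (allowed, stackE, termE, nickb, hp, bu, il, ml_a, ml_b, ml_c,
     maxloop) = pre
    pairs = []
    stack = [("WX", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i >= j:
            continue
        if state == "WX":
            t = WX[i, j]
            if abs(WX[i, j - 1] - t) < _EPS:
                stack.append(("WX", i, j - 1))
                continue
            done = False
            for k in range(i, j):
                if allowed[k, j] and V[k, j] < INF:
                    e = V[k, j] + termE[k, j] + (WX[i, k - 1] if k > i else 0)
                    if abs(e - t) < _EPS:
                        stack.append(("V", k, j))
                        if k > i:
                            stack.append(("WX", i, k - 1))
                        done = True
                        break
            if not done and allowed[i, j] and abs(V[i, j] + termE[i, j] - t) < _EPS:
                stack.append(("V", i, j))
        elif state == "V":
            pairs.append((i, j))
            t = V[i, j]
            nickfree = not any(nickb[b] for b in range(i, j))
            if nickfree and j - i - 1 >= 3 \
                    and abs(hp[j - i - 1] + termE[i, j] - t) < _EPS:
                continue
            if not nickfree:
                hit = False
                for b in range(i, j):
                    if not nickb[b]:
                        continue
                    e = termE[i, j]
                    if b >= i + 1:
                        e += WX[i + 1, b]
                    if b + 1 <= j - 1:
                        e += WX[b + 1, j - 1]
                    if abs(e - t) < _EPS:
                        if b >= i + 1:
                            stack.append(("WX", i + 1, b))
                        if b + 1 <= j - 1:
                            stack.append(("WX", b + 1, j - 1))
                        hit = True
                        break
                if hit:
                    continue
            if stackE[i, j] < INF and V[i + 1, j - 1] < INF \
                    and abs(stackE[i, j] + V[i + 1, j - 1] - t) < _EPS:
                stack.append(("V", i + 1, j - 1))
                continue
            hit = False
            if not nickb[i] and not nickb[j - 1]:
                kmax = min(i + 1 + maxloop, j - 2)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    if k - 1 > i and nickb[k - 1]:
                        break
                    lmin = max(k + 1, j - 1 - (maxloop - s1))
                    for l in range(j - 1, lmin - 1, -1):
                        s2 = j - l - 1
                        if s1 + s2 == 0:
                            continue
                        if l < j - 1 and nickb[l]:
                            break
                        if not allowed[k, l] or V[k, l] >= INF:
                            continue
                        lp = bu[s1 + s2] if (s1 == 0 or s2 == 0) else il[s1 + s2]
                        if abs(lp + termE[i, j] + termE[k, l] + V[k, l] - t) < _EPS:
                            stack.append(("V", k, l))
                            hit = True
                            break
                    if hit:
                        break
            if hit:
                continue
            if not nickb[i] and not nickb[j - 1] and j - i >= 2 \
                    and abs(ml_a + ml_b + termE[i, j] + M2[i + 1, j - 1] - t) < _EPS:
                stack.append(("M2", i + 1, j - 1))
                continue
            raise AssertionError(f"traceback failed at V({i},{j})")
        elif state == "M":
            t = M[i, j]
            if allowed[i, j] and abs(V[i, j] + termE[i, j] + ml_b - t) < _EPS:
                stack.append(("V", i, j))
                continue
            if not nickb[j - 1] and abs(M[i, j - 1] + ml_c - t) < _EPS:
                stack.append(("M", i, j - 1))
                continue
            if not nickb[i] and abs(M[i + 1, j] + ml_c - t) < _EPS:
                stack.append(("M", i + 1, j))
                continue
            hit = False
            for k in range(i + 1, j):
                if nickb[k - 1]:
                    continue
                if M[i, k - 1] < INF and allowed[k, j] and V[k, j] < INF \
                        and abs(M[i, k - 1] + V[k, j] + termE[k, j] + ml_b - t) < _EPS:
                    stack.append(("M", i, k - 1))
                    stack.append(("V", k, j))
                    hit = True
                    break
            if not hit:
                raise AssertionError(f"traceback failed at M({i},{j})")
        elif state == "M2":
            t = M2[i, j]
            if not nickb[j - 1] and abs(M2[i, j - 1] + ml_c - t) < _EPS:
                stack.append(("M2", i, j - 1))
                continue
            hit = False
            for k in range(i + 1, j):
                if nickb[k - 1]:
                    continue
                if M[i, k - 1] < INF and allowed[k, j] and V[k, j] < INF \
                        and abs(M[i, k - 1] + V[k, j] + termE[k, j] + ml_b - t) < _EPS:
                    stack.append(("M", i, k - 1))
                    stack.append(("V", k, j))
                    hit = True
                    break
            if not hit:
                raise AssertionError(f"traceback failed at M2({i},{j})")
    return pairs


def fold_mfe(strands, cond: Conditions | None = None,
             params: NearestNeighborParams | None = None,
             max_len: int = DEFAULT_MAX_LEN,
             max_strands: int = DEFAULT_MAX_STRANDS,
             forbid_pairs=(), forbid_positions=()) -> SecondaryStructure:
    """MFE structure of an ordered strand list under the shipped model.

    ``forbid_pairs`` / ``forbid_positions`` mask the DP for constrained
    refolding (used by the design acceptance check).  The returned
    structure's ``dG`` equals ``structure_energy`` of its pair set exactly.
    """
    if isinstance(strands, Strand):
        strands = [strands]
    strands = tuple(strands)
    cond = cond or Conditions()
    params = params or load_params()
    n = sum(len(s) for s in strands)
    if n > max_len:
        raise FoldResourceError(f"total length {n} exceeds cap {max_len}")
    if not (1 <= len(strands) <= max_strands):
        raise FoldResourceError(
            f"{len(strands)} strands exceeds cap {max_strands}")

    (seq, allowed, stackE, termE, nickb, hp, bu, il, ml_a, ml_b, ml_c,
     assoc) = _precompute(strands, cond, params, forbid_pairs,
                          forbid_positions)
    if n == 1:
        return SecondaryStructure(strands, frozenset(), assoc)
    V, M, M2, WX = _fill(n, allowed, stackE, termE, nickb, hp, bu, il,
                         ml_a, ml_b, ml_c, MAXLOOP)
    pairs = _traceback(n, (V, M, M2, WX),
                       (allowed, stackE, termE, nickb, hp, bu, il,
                        ml_a, ml_b, ml_c, MAXLOOP))
    from .structure import structure_energy
    s = SecondaryStructure(strands, frozenset(pairs))
    dg = structure_energy(s, cond, params, validate=False)
    dp_dg = WX[0, n - 1] + assoc
    if abs(dg - dp_dg) > 1e-4:
        raise AssertionError(
            f"DP/scorer disagreement: {dp_dg:.4f} vs {dg:.4f} "
            f"({'+'.join(x.name for x in strands)})")
    return s.with_dg(dg)


def fold_matrices(strands, cond=None, params=None):
    """DP tables plus precomputed arrays (for suboptimal enumeration)."""
    strands = (strands,) if isinstance(strands, Strand) else tuple(strands)
    cond = cond or Conditions()
    params = params or load_params()
    n = sum(len(s) for s in strands)
    (seq, allowed, stackE, termE, nickb, hp, bu, il, ml_a, ml_b, ml_c,
     assoc) = _precompute(strands, cond, params)
    V, M, M2, WX = _fill(n, allowed, stackE, termE, nickb, hp, bu, il,
                         ml_a, ml_b, ml_c, MAXLOOP)
    return {
        "n": n, "V": V, "M": M, "M2": M2, "WX": WX, "allowed": allowed,
        "stackE": stackE, "termE": termE, "nickb": nickb, "hp": hp,
        "bu": bu, "il": il, "ml": (ml_a, ml_b, ml_c), "assoc": assoc,
        "maxloop": MAXLOOP,
    }
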