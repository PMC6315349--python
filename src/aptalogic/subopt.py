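"""Enumeration of suboptimal structures within a relative energy window.

Implements Wuchty-style enumeration on top of the folding DP tables: a
partial solution is a set of fixed pairs, an accumulated energy, and a list
of unresolved DP states; a partial is expanded only while its optimal
completion stays within the window.  The window is relative to the MFE:
every structure with

    dG <= dG_mfe + window * |dG_mfe|

is returned (deduplicated by pair set, ascending in energy, the MFE
structure first).  Used by the designer's acceptance rule, which asks
whether any structure within 20 % of the MFE departs from the desired
conformation.
"""

from __future__ import annotations

from .fold import INF, fold_matrices
from .params import NearestNeighborParams, load_params
from .strands import Conditions, Strand
from .structure import SecondaryStructure

_EPS = 1e-9


class SuboptOverflowError(RuntimeError):
    """More structures in the window than the configured cap."""


def enumerate_suboptimal(strands, cond: Conditions | None = None,
                         window: float = 0.20,
                         params: NearestNeighborParams | None = None,
                         max_structures: int = 50000):
    """All structures within ``window``·|dG_mfe| of the MFE, best first."""
    if not (0.0 < window <= 1.0):
        raise ValueError("window must be in (0, 1]")
    if isinstance(strands, Strand):
        strands = (strands,)
    strands = tuple(strands)
    cond = cond or Conditions()
    params = params or load_params()

    mats = fold_matrices(strands, cond, params)
    n = mats["n"]
    V, M, M2, WX = mats["V"], mats["M"], mats["M2"], mats["WX"]
    allowed, stackE, termE = mats["allowed"], mats["stackE"], mats["termE"]
    nickb = mats["nickb"]
    hp, bu, il = mats["hp"], mats["bu"], mats["il"]
    ml_a, ml_b, ml_c = mats["ml"]
    assoc = mats["assoc"]
    maxloop = mats["maxloop"]

    if n == 1:
        return [SecondaryStructure(strands, frozenset(), assoc)]

    mfe = WX[0, n - 1] + assoc
    thr = mfe + window * abs(mfe) + _EPS

    def opt(state):
        kind, i, j = state
        if i >= j:
            return 0.0 if kind in ("WX",) else INF
        return {"WX": WX, "V": V, "M": M, "M2": M2}[kind][i, j]

    results: dict[frozenset, float] = {}
    # partial: (fixed_energy, pairs tuple, pending states tuple)
    work = [(assoc, (), (("WX", 0, n - 1),))]
    while work:
        fixed, pairs, pending = work.pop()
        if not pending:
            key = frozenset(pairs)
            if key not in results or fixed < results[key]:
                results[key] = fixed
            if len(results) > max_structures:
                raise SuboptOverflowError(
                    f"more than {max_structures} structures in window")
            continue
        state, rest = pending[0], pending[1:]
        kind, i, j = state
        base = fixed + sum(opt(s) for s in rest)

        def push(extra, new_pairs, new_states):
            b = base + extra + sum(opt(s) for s in new_states)
            if b <= thr:
                work.append((fixed + extra, pairs + tuple(new_pairs),
                             tuple(new_states) + rest))

        if i >= j:
            if kind == "WX":
                push(0.0, (), ())
            continue

        if kind == "WX":
            # j unpaired
            if j - 1 >= i:
                push(0.0, (), (("WX", i, j - 1),))
            else:
                push(0.0, (), ())
            # j paired to k
            for k in range(i, j):
                if allowed[k, j] and V[k, j] < INF:
                    states = [("V", k, j)]
                    if k > i:
                        states.append(("WX", i, k - 1))
                    push(termE[k, j], (), states)
        elif kind == "V":
            nickfree = not any(nickb[b] for b in range(i, j))
            if nickfree and j - i - 1 >= 3:
                push(hp[j - i - 1] + termE[i, j], [(i, j)], ())
            if not nickfree:
                for b in range(i, j):
                    if not nickb[b]:
                        continue
                    states = []
                    if b >= i + 1:
                        states.append(("WX", i + 1, b))
                    if b + 1 <= j - 1:
                        states.append(("WX", b + 1, j - 1))
                    push(termE[i, j], [(i, j)], states)
            if stackE[i, j] < INF and V[i + 1, j - 1] < INF:
                push(stackE[i, j], [(i, j)], (("V", i + 1, j - 1),))
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
                        lp = bu[s1 + s2] if (s1 == 0 or s2 == 0) \
                            else il[s1 + s2]
                        push(lp + termE[i, j] + termE[k, l], [(i, j)],
                             (("V", k, l),))
                if j - i >= 2 and M2[i + 1, j - 1] < INF:
                    push(ml_a + ml_b + termE[i, j], [(i, j)],
                         (("M2", i + 1, j - 1),))
        elif kind == "M":
            if not nickb[j - 1] and M[i, j - 1] < INF:
                push(ml_c, (), (("M", i, j - 1),))
            for k in range(i, j):
                if not (allowed[k, j] and V[k, j] < INF):
                    continue
                if k == i:
                    push(termE[k, j] + ml_b, (), (("V", k, j),))
                else:
                    # all-unpaired prefix [i, k-1]
                    if not any(nickb[b] for b in range(i, k)):
                        push(termE[k, j] + ml_b + ml_c * (k - i), (),
                             (("V", k, j),))
                    # >=1 branch prefix
                    if not nickb[k - 1] and M[i, k - 1] < INF:
                        push(termE[k, j] + ml_b, (),
                             (("V", k, j), ("M", i, k - 1)))
        elif kind == "M2":
            if not nickb[j - 1] and M2[i, j - 1] < INF:
                push(ml_c, (), (("M2", i, j - 1),))
            for k in range(i + 1, j):
                if nickb[k - 1]:
                    continue
                if M[i, k - 1] < INF and allowed[k, j] and V[k, j] < INF:
                    push(termE[k, j] + ml_b, (),
                         (("V", k, j), ("M", i, k - 1)))

    structures = [
        SecondaryStructure(strands, key, e)
        for key, e in results.items() if e <= thr
    ]
    structures.sort(key=lambda s: (s.dG, s.to_dot_bracket()))
    return structures
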