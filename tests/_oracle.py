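"""Exhaustive folding oracle for short sequences.

Enumerates every legal non-pseudoknotted structure (each position in at
most one pair, Watson-Crick or RNA wobble pairing, hairpin loops of at
least three unpaired nucleotides unless interrupted by a nick) and scores
each with the public loop-decomposition scorer.  Completely independent of
the dynamic program it is used to check.
"""

from __future__ import annotations

from aptalogic.strands import Conditions, can_pair
from aptalogic.structure import SecondaryStructure, structure_energy


def enumerate_structures(strands) -> list[SecondaryStructure]:
    """All legal structures over the ordered strand list."""
    from aptalogic.strands import Strand
    if isinstance(strands, Strand):
        strands = (strands,)
    strands = tuple(strands)
    seq = "".join(s.sequence for s in strands)
    polymers = []
    for s in strands:
        polymers.extend([s.polymer] * len(s))
    n = len(seq)
    nicks = set()
    pos = 0
    for s in strands[:-1]:
        pos += len(s)
        nicks.add(pos - 1)

    def pair_ok(i, j):
        if not can_pair(seq[i], seq[j], polymers[i], polymers[j]):
            return False
        if j - i - 1 >= 3:
            return True
        return any(i <= b < j for b in nicks)

    memo: dict = {}

    def region(i, j):
        """List of pair-tuples for region [i, j]."""
        if i >= j:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [(() + r) for r in region(i + 1, j)]  # i unpaired
        for k in range(i + 1, j + 1):
            if not pair_ok(i, k):
                continue
            for inner in region(i + 1, k - 1):
                for rest in region(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        memo[key] = out
        return out

    return [SecondaryStructure(strands, frozenset(p))
            for p in region(0, n - 1)]


def brute_force_mfe(strands, cond: Conditions | None = None):
    """(best structure, energy) by exhaustive enumeration + scoring."""
    cond = cond or Conditions()
    best, best_e = None, None
    for s in enumerate_structures(strands):
        e = structure_energy(s, cond, validate=False)
        if best_e is None or e < best_e - 1e-12:
            best, best_e = s, e
    return best.with_dg(best_e), best_e
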