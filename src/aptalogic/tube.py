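"""Complex enumeration and equilibrium concentrations in a test tube.

Every distinct strand multiset up to a size cap is a candidate complex;
its representative structure is the multiset's MFE over the best circular
strand ordering (each complex is represented by that single structure, so
ON/OFF classification of a species is unambiguous).  Species whose MFE has
no inter-strand pair are dropped, except monomers, which are always kept.

Equilibrium solves the law-of-mass-action fixed point

    x_j = exp(-ΔG_j / RT) · Π_s λ_s^{ν_sj}

for the free-strand activities λ_s under per-strand mass conservation,
equivalently minimizing the tube free energy.  A damped Newton iteration
in log-activity space is used; the analytic closed form of a single
dimerization is reproduced to solver tolerance (tested).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fold import fold_mfe
from .params import NearestNeighborParams, R_GAS, load_params
from .strands import Conditions
from .structure import SecondaryStructure

MAX_COMPLEX_SIZE = 4


class TubeError(ValueError):
    """Invalid tube problem (cap out of range, missing strand...)."""


class ConvergenceError(RuntimeError):
    """Equilibrium solver failed to reach tolerance."""


@dataclass(frozen=True)
class ComplexSpecies:
    """A strand multiset with its representative (MFE) structure."""

    strand_counts: tuple          # sorted ((name, count), ...)
    structure: SecondaryStructure  # strands in the folded ordering
    dG: float                      # kcal/mol, equals structure.dG

    @property
    def name(self) -> str:
        return "+".join(f"{c}x{n}" if c > 1 else n
                        for n, c in self.strand_counts)

    @property
    def size(self) -> int:
        return sum(c for _, c in self.strand_counts)

    def count_of(self, strand_name: str) -> int:
        return dict(self.strand_counts).get(strand_name, 0)


@dataclass(frozen=True)
class TubeState:
    """Equilibrium concentrations (M) for an enumerated species list."""

    species: tuple
    concentrations: tuple          # M, same order as species
    conditions: Conditions

    def concentration_of(self, species_name: str) -> float:
        for sp, c in zip(self.species, self.concentrations):
            if sp.name == species_name:
                return c
        raise KeyError(species_name)

    def strand_total(self, strand_name: str) -> float:
        return sum(sp.count_of(strand_name) * c
                   for sp, c in zip(self.species, self.concentrations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": [sp.name for sp in self.species],
            "n_strands": [sp.size for sp in self.species],
            "dG_kcal_mol": [sp.dG for sp in self.species],
            "concentration_M": list(self.concentrations),
            "structure": [sp.structure.to_dot_bracket()
                          for sp in self.species],
        })


def _circular_orderings(names: tuple) -> list[tuple]:
    """Distinct circular orderings (necklaces) of a strand-name multiset."""
    seen, out = set(), []
    for perm in sorted(set(itertools.permutations(names))):
        canon = min(perm[i:] + perm[:i] for i in range(len(perm)))
        if canon not in seen:
            seen.add(canon)
            out.append(perm)
    return out


def _has_interstrand_pair(s: SecondaryStructure) -> bool:
    offsets = s.strand_offsets()
    ends = [o + len(st) for o, st in zip(offsets, s.strands)]

    def strand_of(i):
        for k, e in enumerate(ends):
            if i < e:
                return k
        raise IndexError(i)

    return any(strand_of(i) != strand_of(j) for i, j in s.pairs)


def enumerate_complexes(strands, max_size: int,
                        cond: Conditions | None = None,
                        params: NearestNeighborParams | None = None):
    """All complexes of the given strands up to ``max_size`` strands."""
    if not (1 <= max_size <= MAX_COMPLEX_SIZE):
        raise TubeError(f"max_size must be in [1, {MAX_COMPLEX_SIZE}]")
    cond = cond or Conditions()
    params = params or load_params()
    by_name = {s.name: s for s in strands}
    if len(by_name) != len(strands):
        raise TubeError("strand names must be unique")
    names = sorted(by_name)

    species = []
    for size in range(1, max_size + 1):
        for multiset in itertools.combinations_with_replacement(names, size):
            best = None
            for ordering in _circular_orderings(multiset):
                folded = fold_mfe([by_name[n] for n in ordering], cond,
                                  params, max_strands=max_size)
                if best is None or folded.dG < best.dG - 1e-12:
                    best = folded
            if size > 1 and not _has_interstrand_pair(best):
                continue
            counts = tuple(sorted(
                (n, multiset.count(n)) for n in set(multiset)))
            species.append(ComplexSpecies(counts, best, best.dG))
    return species


def solve_equilibrium(species, totals: dict,
                      cond: Conditions | None = None,
                      tol: float = 1e-9, max_iter: int = 10000) -> TubeState:
    """Equilibrium TubeState for the species list at given strand totals (M)."""
    cond = cond or Conditions()
    strand_names = sorted(totals)
    for name, total in totals.items():
        if total <= 0:
            raise TubeError(f"total of {name!r} must be positive")
        if not any(sp.count_of(name) for sp in species):
            raise TubeError(f"strand {name!r} appears in no species")
    for sp in species:
        for name, _ in sp.strand_counts:
            if name not in totals:
                raise TubeError(f"species {sp.name} uses strand {name!r} "
                                f"with no total concentration")

    rt = R_GAS * cond.kelvin
    nu = np.array([[sp.count_of(n) for sp in species]
                   for n in strand_names], dtype=float)   # (S, J)
    logk = np.array([-sp.dG / rt for sp in species])
    b = np.array([totals[n] for n in strand_names])

    # Newton with Armijo backtracking on the convex dual objective
    #   F(t) = sum_j x_j(t) - b·t,   x_j(t) = exp(logk_j + nu_j·t),
    # whose unique minimum is the equilibrium (grad F = supply - b).
    def x_of(tvec):
        return np.exp(np.minimum(logk + nu.T @ tvec, 600.0))

    def obj(tvec):
        return float(np.sum(x_of(tvec)) - b @ tvec)

    # start with each strand's activity at its total, then pull down hard
    # so the initial supplies are finite and modest
    t = np.log(b)
    for _ in range(200):
        if np.max(nu @ x_of(t)) < 10.0 * np.max(b):
            break
        t -= 1.0

    x = x_of(t)
    stalls = 0
    for _ in range(max_iter):
        sup = nu @ x
        grad = sup - b
        if np.max(np.abs(grad) / b) < 1e-11:
            break
        hess = (nu * x) @ nu.T
        try:
            step = np.linalg.solve(
                hess + 1e-14 * np.eye(len(b)) * np.trace(hess), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        f0 = obj(t)
        alpha, decrease = 1.0, grad @ step
        while alpha > 1e-14:
            if obj(t - alpha * step) <= f0 - 1e-4 * alpha * decrease:
                break
            alpha *= 0.5
        t = t - alpha * step
        x = x_of(t)
        stalls = stalls + 1 if obj(t) >= f0 - abs(f0) * 1e-15 else 0
        if stalls >= 5:
            break  # numerically converged (no further descent possible)
    sup = nu @ x
    if np.max(np.abs(sup - b) / b) > 1e-6 and np.max(np.abs(sup - b)) > tol:
        raise ConvergenceError(
            f"equilibrium solver: relative residual "
            f"{np.max(np.abs(sup - b) / b):.2e}")

    resid = np.max(np.abs(sup - b) / b)
    if resid > 1e-6:
        raise ConvergenceError(f"mass-balance residual {resid:.2e} > 1e-6")
    return TubeState(tuple(species), tuple(x), cond)
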