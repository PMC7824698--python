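"""Monomial (Taylor) lifting of macro-parameters and pair-difference features.

A degree-``k`` Taylor form of fitness in ``n`` macro-parameters,
``F = Σ λ_{i1..in} M1^{i1} ... Mn^{in}`` (total degree 1..k), is linear in
the lifted monomial features ``Q_{i1..in} = M1^{i1}...Mn^{in}``. Ranking a
pair of strategies (v, w) then reduces to the sign of ``λ · (P(v) - P(w))``,
i.e. to linear classification of pair-difference vectors by an
origin-through hyperplane whose normal is the coefficient vector λ.

The canonical basis order used everywhere in this package is graded
lexicographic: ascending total degree, then lexicographic on the exponent
tuple. The length of the basis is ``C(n+k, k) - 1`` (the constant monomial
is excluded — it cancels in every pair difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .trajectories import MacroParams

__all__ = [
    "multi_indices",
    "lift",
    "pair_feature",
    "fitness_value",
    "FitnessCoefficients",
    "RankedPair",
]


def multi_indices(n: int, k: int) -> list[tuple[int, ...]]:
    """All exponent tuples of total degree 1..k over n variables.

    Graded order: ascending total degree; inside a degree block the tuples
    run in descending lexicographic order, so the linear slots come out as
    M1, M2, ..., Mn and e.g. n=2, k=2 gives
    [(1,0), (0,1), (2,0), (1,1), (0,2)]. Deterministic; length C(n+k,k) - 1.
    """
    if n < 1 or k < 1:
        raise ValueError(f"need n >= 1 and k >= 1, got n={n}, k={k}")
    out: list[tuple[int, ...]] = []
    for degree in range(1, k + 1):
        block = [idx for idx in product(range(degree, -1, -1), repeat=n)
                 if sum(idx) == degree]
        block.sort(reverse=True)
        out.extend(block)
    return out


def lift(M: MacroParams | Sequence[float], k: int,
         basis: list[tuple[int, ...]] | None = None) -> np.ndarray:
    """Monomial features Q of a macro-parameter vector, canonical order."""
    values = M.values if isinstance(M, MacroParams) else np.asarray(M, dtype=float)
    if basis is None:
        basis = multi_indices(values.size, k)
    Q = np.array([np.prod(values ** np.asarray(idx)) for idx in basis])
    if not np.all(np.isfinite(Q)):
        raise OverflowError("monomial lifting overflowed; rescale the inputs")
    return Q


def pair_feature(Pv: np.ndarray, Pw: np.ndarray) -> np.ndarray:
    """Difference feature P(v) - P(w); antisymmetric by construction."""
    Pv, Pw = np.asarray(Pv, dtype=float), np.asarray(Pw, dtype=float)
    if Pv.shape != Pw.shape:
        raise ValueError(f"feature basis mismatch: {Pv.shape} vs {Pw.shape}")
    return Pv - Pw


@dataclass(frozen=True)
class FitnessCoefficients:
    """Taylor coefficients λ over the canonical monomial basis.

    A fitness is only defined up to a positive scale; ``normalization``
    records which gauge the stored vector is in ("raw", "unit", or "match").
    """

    lambdas: np.ndarray
    n: int
    k: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        expected = len(multi_indices(self.n, self.k))
        if lam.shape != (expected,):
            raise ValueError(
                f"coefficient vector has length {lam.size}, expected {expected} "
                f"for n={self.n}, k={self.k}"
            )
        if not np.all(np.isfinite(lam)):
            raise ValueError("non-finite fitness coefficients")
        object.__setattr__(self, "lambdas", lam)

    @property
    def basis(self) -> list[tuple[int, ...]]:
        return multi_indices(self.n, self.k)

    def unit(self) -> "FitnessCoefficients":
        """Gauge-fix: unit L2 norm with a non-negative M1 coefficient."""
        lam = self.lambdas
        norm = float(np.linalg.norm(lam))
        if norm == 0:
            raise ZeroDivisionError("cannot normalize an all-zero coefficient vector")
        lam = lam / norm
        if lam[0] < 0:
            lam = -lam
        return FitnessCoefficients(lam, self.n, self.k, "unit")


@dataclass(frozen=True)
class RankedPair:
    """A labelled pair difference: diff = P(v) - P(w), label +1 iff v ≻ w."""

    diff: np.ndarray
    label: int
    direction: int = -1
    eps_v: float = np.nan
    eps_w: float = np.nan

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        object.__setattr__(self, "diff", np.asarray(self.diff, dtype=float))


def fitness_value(M: MacroParams | Sequence[float],
                  coeffs: FitnessCoefficients) -> float:
    """Evaluate the Taylor fitness F = λ · lift(M)."""
    values = M.values if isinstance(M, MacroParams) else np.asarray(M, dtype=float)
    if values.size != coeffs.n:
        raise ValueError(
            f"macro-parameter length {values.size} does not match basis n={coeffs.n}"
        )
    return float(coeffs.lambdas @ lift(values, coeffs.k, coeffs.basis))
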