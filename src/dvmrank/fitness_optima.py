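"""Closed-form DVM optima for the lin-quad environment and fitness forms.

With linear food/predation profiles and a quadratic depth penalty, the
linear fitness

    F = alpha*M1 + gamma*M2 + beta*M3 + delta*M4

is maximized over periodic trajectories by a pure daily cosine
``x*(t) = A + B cos(2*pi*t)`` whose mean depth and half-amplitude follow in
closed form:

    A = (sigma1*alpha - sigma2*gamma) / (2*delta) - C0
    B = -sigma2*gamma / (2*delta + 2*(2*pi)**2 * beta)

(B < 0: the animal is deepest when the visual predators are most active).
The macro-parameters of any cosine trajectory also have closed forms, which
serve as the exact oracle for both the quadrature functionals and the
numerical optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .environment import EnvironmentModel, LinQuadEnv
from .feature_space import FitnessCoefficients, multi_indices
from .trajectories import MacroParams

__all__ = [
    "LinearFitnessCoeffs",
    "QuadraticFitnessCoeffs",
    "CosineOptimum",
    "closed_form_optimum",
    "cosine_macro_params",
    "quadratic_fitness",
]

TWO_PI_SQ = (2.0 * np.pi) ** 2


def study_coefficients(family: str) -> "LinearFitnessCoeffs":
    """Reported linear-fitness coefficient sets for the two environments."""
    table = {
        "lin-quad": dict(alpha=1.96, gamma=3.3e2, beta=2.5e-5, delta=1e-2),
        "hyperbolic": dict(alpha=2.5, gamma=3.33e2, beta=7.5e-9, delta=1e-5),
    }
    if family not in table:
        raise KeyError(f"no reported coefficients for family {family!r}")
    return LinearFitnessCoeffs(**table[family])


@dataclass(frozen=True)
class LinearFitnessCoeffs:
    """Positive weights of (M1, M2, M3, M4): food, predation, cost, depth.

    Printed order convention: alpha*M1 + gamma*M2 + beta*M3 + delta*M4.
    Only the ratios matter for ranking (positive-scale invariance).
    """

    alpha: float
    gamma: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "beta", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_vector(self) -> np.ndarray:
        """Coefficients in macro-parameter slot order (M1, M2, M3, M4)."""
        return np.array([self.alpha, self.gamma, self.beta, self.delta])

    def as_fitness_coefficients(self) -> FitnessCoefficients:
        return FitnessCoefficients(self.as_vector(), n=4, k=1)


@dataclass(frozen=True)
class QuadraticFitnessCoeffs:
    """Quadratic two-stage fitness: linear lam_i plus symmetric lam_ij.

    ``quadratic[i, j]`` stores the coefficient of M_i*M_j once (upper
    triangle, i <= j); evaluation expands it symmetrically.
    """

    linear: np.ndarray     # shape (8,)
    quadratic: np.ndarray  # shape (8, 8), upper triangle meaningful

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float)
        quad = np.asarray(self.quadratic, dtype=float)
        if lin.shape != (8,) or quad.shape != (8, 8):
            raise ValueError("need linear shape (8,) and quadratic shape (8, 8)")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "quadratic", np.triu(quad))

    def as_fitness_coefficients(self) -> FitnessCoefficients:
        """Map to the canonical degree-2 monomial basis (n=8, k=2)."""
        basis = multi_indices(8, 2)
        lam = np.zeros(len(basis))
        for pos, idx in enumerate(basis):
            nz = [i for i, e in enumerate(idx) if e]
            if sum(idx) == 1:
                lam[pos] = self.linear[nz[0]]
            elif len(nz) == 1:        # square term M_i^2
                lam[pos] = self.quadratic[nz[0], nz[0]]
            else:                     # cross term M_i*M_j, i < j
                lam[pos] = self.quadratic[nz[0], nz[1]]
        return FitnessCoefficients(lam, n=8, k=2)


@dataclass(frozen=True)
class CosineOptimum:
    """Cosine trajectory parameters: mean depth A and half-amplitude B (m)."""

    A: float
    B: float

    def __call__(self, t):
        return self.A + self.B * np.cos(2.0 * np.pi * np.asarray(t))

    def derivative(self, t):
        return -2.0 * np.pi * self.B * np.sin(2.0 * np.pi * np.asarray(t))


def _linquad_params(env) -> LinQuadEnv:
    p = env.params if isinstance(env, EnvironmentModel) else env
    if not isinstance(p, LinQuadEnv):
        raise TypeError("closed forms exist only for the lin-quad environment")
    return p


def closed_form_optimum(coeffs: LinearFitnessCoeffs, env,
                        cadence: int | None = None) -> CosineOptimum:
    """Exact fitness-maximizing cosine trajectory in a lin-quad environment.

    With ``cadence=L`` the optimum of the *L-point discrete* fitness
    (plain sums, central-difference velocity) is returned instead: the
    circulant structure keeps it a daily cosine with the same mean depth,
    but the migration-cost term sees the central-difference attenuation
    ``sinc(2*pi/L)**2`` of the fundamental mode, which slightly enlarges
    the amplitude. The discrete optimum is the right base for the
    ε-perturbation generator, whose ranking rule presumes the base
    maximizes the sampled fitness.
    """
    p = _linquad_params(env)
    if coeffs.delta == 0:
        raise ZeroDivisionError(
            "delta = 0 leaves the mean-depth problem unbounded")
    attenuation = 1.0
    if cadence is not None:
        if cadence < 4:
            raise ValueError("cadence must be at least 4 samples per day")
        w = 2.0 * np.pi / cadence
        attenuation = (np.sin(w) / w) ** 2
    A = (p.sigma1 * coeffs.alpha - p.sigma2 * coeffs.gamma) / (2.0 * coeffs.delta) - p.C0
    B = -p.sigma2 * coeffs.gamma / (
        2.0 * coeffs.delta + 2.0 * TWO_PI_SQ * coeffs.beta * attenuation)
    if A + abs(B) > 0 or A - abs(B) <= -p.C:
        warnings.warn(
            f"closed-form optimum (A={A:.2f}, B={B:.2f}) leaves the column "
            f"(-{p.C:g}, 0]; the unconstrained formulas are returned as-is",
            stacklevel=2)
    return CosineOptimum(A=A, B=B)


def cosine_macro_params(opt: CosineOptimum, env) -> MacroParams:
    """Closed-form integral macro-parameters of a cosine trajectory.

    M1 = sigma1 (A + C); M2 = -sigma2 (A + C + B/2); M3 = -(2*pi)^2 B^2 / 2;
    M4 = -((A + C0)^2 + B^2 / 2).
    """
    p = _linquad_params(env)
    A, B = opt.A, opt.B
    return MacroParams(np.array([
        p.sigma1 * (A + p.C),
        -p.sigma2 * (A + p.C + B / 2.0),
        -TWO_PI_SQ * B ** 2 / 2.0,
        -((A + p.C0) ** 2 + B ** 2 / 2.0),
    ]))


def quadratic_fitness(M: MacroParams | np.ndarray,
                      coeffs: QuadraticFitnessCoeffs) -> float:
    """Evaluate the two-stage quadratic fitness at an 8-vector M."""
    values = M.values if isinstance(M, MacroParams) else np.asarray(M, dtype=float)
    if values.shape != (8,):
        raise ValueError(f"need an 8-vector of macro-parameters, got {values.shape}")
    lin = float(coeffs.linear @ values)
    quad = float(values @ np.triu(coeffs.quadratic) @ values)
    return lin + quad
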