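"""Periodic daily depth trajectories and their macro-parameter functionals.

A strategy is a 1-periodic depth path ``x(t)`` (t in day fractions). From a
trajectory and an environment we compute the macro-parameters that drive
population success:

* ``M1``  daily food intake, integral of ``E(x(t))``;
* ``M2``  (minus) daily visual-predation mortality, ``-∫ St(t) Sx(x(t)) dt``;
* ``M3``  (minus) metabolic cost of migration, ``-∫ x'(t)^2 dt``;
* ``M4``  (minus) unfavourable-depth mortality, ``-∫ G(x(t)) dt``.

For a two-stage (juvenile, adult) strategy the same four functionals of the
adult path become ``M5..M8``. Discrete sums over ``L`` equispaced day times
(the field cadence is L=8, i.e. every 3 h) deliberately omit the common
``Δt`` factor — this rescales all fitness coefficients by the same positive
constant and leaves the ranking untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import quad

from .environment import DomainError, EnvironmentModel

__all__ = [
    "Trajectory",
    "StagePair",
    "MacroParams",
    "cosine_trajectory",
    "macro_params_discrete",
    "macro_params_integral",
]

DEFAULT_L = 8  # 3-hourly sampling


@dataclass(frozen=True)
class Trajectory:
    """Depths sampled at L equispaced day fractions t_l = l/L, l=0..L-1.

    Periodicity is implicit: t=1 wraps to t=0, so x(1)=x(0) by construction.
    """

    samples: np.ndarray
    stage: str = "unstaged"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 4:
            raise ValueError("a trajectory needs at least L=4 depth samples")
        object.__setattr__(self, "samples", samples)
        if self.stage not in ("juvenile", "adult", "unstaged"):
            raise ValueError(f"unknown stage label {self.stage!r}")

    @property
    def L(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.L) / self.L

    def velocity(self) -> np.ndarray:
        """Central-difference x'(t_l) with periodic wraparound."""
        dt = 1.0 / self.L
        return (np.roll(self.samples, -1) - np.roll(self.samples, 1)) / (2.0 * dt)


@dataclass(frozen=True)
class StagePair:
    """Juvenile and adult daily trajectories with a common sampling grid."""

    juvenile: Trajectory
    adult: Trajectory

    def __post_init__(self) -> None:
        if self.juvenile.L != self.adult.L:
            raise ValueError("juvenile and adult trajectories must share L")


@dataclass(frozen=True)
class MacroParams:
    """Ordered macro-parameter vector (M1..M4) or (M1..M8)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape not in ((4,), (8,)):
            raise ValueError("macro-parameter vector must have length 4 or 8")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size


def cosine_trajectory(A: float, B: float, L: int = DEFAULT_L,
                      stage: str = "unstaged", C: float = 140.0) -> Trajectory:
    """Sample the cosine path ``x(t) = A + B cos(2*pi*t)`` at L day times.

    ``A`` is the mean depth (signed, metres), ``B`` the half-amplitude.
    Raises :class:`DomainError` if the path leaves ``(-C, 0]``.
    """
    if A + abs(B) > 0:
        raise DomainError(f"trajectory surfaces: A+|B| = {A + abs(B):g} > 0")
    if A - abs(B) <= -C:
        raise DomainError(f"trajectory hits bottom: A-|B| = {A - abs(B):g} <= -C")
    t = np.arange(L) / L
    return Trajectory(A + B * np.cos(2.0 * np.pi * t), stage=stage)


def _discrete_four(traj: Trajectory, env: EnvironmentModel) -> np.ndarray:
    env.check_domain(traj.samples)
    p = env.params
    x, t = traj.samples, traj.times
    m1 = float(np.sum(p.E(x)))
    m2 = -float(np.sum(env.St(t) * p.Sx(x)))
    m3 = -float(np.sum(traj.velocity() ** 2))
    m4 = -float(np.sum(p.G(x)))
    return np.array([m1, m2, m3, m4])


def macro_params_discrete(traj: Union[Trajectory, StagePair],
                          env: EnvironmentModel) -> MacroParams:
    """Macro-parameters as plain sums over the trajectory's sample grid.

    No ``Δt`` multiplier is applied (see module docstring); divide by L to
    compare against the integral form.
    """
    if isinstance(traj, StagePair):
        return MacroParams(np.concatenate([
            _discrete_four(traj.juvenile, env),
            _discrete_four(traj.adult, env),
        ]))
    return MacroParams(_discrete_four(traj, env))


def macro_params_integral(x_fn, env: EnvironmentModel,
                          quad_tol: float = 1e-10,
                          adult_fn: Callable[[float], float] | None = None,
                          dx_fn: Callable[[float], float] | None = None,
                          adult_dx_fn: Callable[[float], float] | None = None,
                          ) -> MacroParams:
    """Macro-parameters of a smooth periodic trajectory by adaptive quadrature.

    ``x_fn`` maps a day fraction to a depth; supply ``adult_fn`` for a
    two-stage strategy (then M5..M8 are appended). Optional analytic
    derivatives ``dx_fn``/``adult_dx_fn`` replace the default central
    finite-difference derivative in the migration-cost integral.
    """
    vals = _integral_four_with_dx(x_fn, dx_fn, env, quad_tol)
    if adult_fn is not None:
        vals = np.concatenate([
            vals, _integral_four_with_dx(adult_fn, adult_dx_fn, env, quad_tol)
        ])
    return MacroParams(vals)


def _integral_four_with_dx(x_fn, dx_fn, env: EnvironmentModel,
                           quad_tol: float) -> np.ndarray:
    if dx_fn is None:
        def dx_fn(t, h=1e-6):
            return (x_fn((t + h) % 1.0) - x_fn((t - h) % 1.0)) / (2.0 * h)
    p = env.params
    integrands = [
        lambda t: p.E(x_fn(t)),
        lambda t: -env.St(t) * p.Sx(x_fn(t)),
        lambda t: -dx_fn(t) ** 2,
        lambda t: -p.G(x_fn(t)),
    ]
    out = []
    for f in integrands:
        val, err = quad(f, 0.0, 1.0, epsabs=quad_tol, epsrel=quad_tol, limit=200)
        if not np.isfinite(val):
            raise ArithmeticError(f"quadrature returned non-finite value {val!r}")
        out.append(val)
    return np.array(out)
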