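"""Finite-strategy selection dynamics and entropy diagnostics.

Grounds the ranking definition operationally: strategy v outranks w when
the density ratio rho_w / rho_v decays to zero under selection. The minimal
dynamic realizing this is replicator-style growth — each strategy's density
is multiplied by exp(F_i * dt) per step and the distribution renormalized —
so log-density ratios drift linearly at the fitness differences. Shannon
entropy of the strategy distribution then decays to zero as selection
concentrates on the single fittest strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrategyDistribution",
    "simulate_selection",
    "empirical_ranking",
    "shannon_entropy",
]


@dataclass(frozen=True)
class StrategyDistribution:
    """Non-negative strategy densities, optionally normalized to sum 1."""

    densities: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        rho = np.asarray(self.densities, dtype=float)
        if rho.ndim != 1 or rho.size < 1:
            raise ValueError("need a 1-D density vector")
        if np.any(rho < 0):
            raise ValueError("densities must be non-negative")
        if self.normalized:
            total = rho.sum()
            if total <= 0:
                raise ValueError("cannot normalize an all-zero distribution")
            rho = rho / total
        object.__setattr__(self, "densities", rho)


def simulate_selection(initial: StrategyDistribution | np.ndarray,
                       fitness: np.ndarray, T: float, dt: float) -> np.ndarray:
    """Replicator time series: rho_i <- rho_i * exp(F_i dt), renormalized.

    Returns an array of shape (n_steps + 1, N) including the initial state.
    Extinct strategies (density 0) stay extinct. Deterministic.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("need T > 0 and dt > 0")
    rho = (initial.densities if isinstance(initial, StrategyDistribution)
           else np.asarray(initial, dtype=float))
    if np.all(rho == 0):
        raise ValueError("all-zero initial distribution")
    F = np.asarray(fitness, dtype=float)
    if F.shape != rho.shape:
        raise ValueError("fitness vector and distribution sizes differ")
    rho = rho / rho.sum()
    n_steps = int(round(T / dt))
    out = np.empty((n_steps + 1, rho.size))
    out[0] = rho
    growth = np.exp(F * dt)
    for step in range(1, n_steps + 1):
        rho = rho * growth
        rho = rho / rho.sum()
        out[step] = rho
    return out


def empirical_ranking(series: np.ndarray, tail_fraction: float = 0.2,
                      slope_threshold: float = 1e-3,
                      dt: float = 1.0) -> set[tuple[int, int]]:
    """Partial order from a density time series via the tail log-slope test.

    Returns the set of pairs (i, j) meaning strategy i outranks strategy j:
    log(rho_j / rho_i) must drift downward faster than ``slope_threshold``
    per unit time over the final ``tail_fraction`` of the series. A strategy
    extinct in the tail while the other survives is declared inferior; pairs
    without a clear drift stay incomparable.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 10:
        raise ValueError("need a (steps >= 10, N) density time series")
    n_steps, N = series.shape
    tail = series[int(np.floor((1.0 - tail_fraction) * n_steps)):]
    t = np.arange(tail.shape[0]) * dt
    order: set[tuple[int, int]] = set()
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            zi, zj = tail[:, i], tail[:, j]
            if np.all(zj == 0) and np.any(zi > 0):
                order.add((i, j))
                continue
            if np.any(zi == 0):
                continue
            with np.errstate(divide="ignore"):
                logratio = np.log(zj) - np.log(zi)
            if not np.all(np.isfinite(logratio)):
                continue
            slope = np.polyfit(t, logratio, 1)[0]
            if slope < -slope_threshold:
                order.add((i, j))
    return order


def shannon_entropy(dist: StrategyDistribution | np.ndarray,
                    atol: float = 1e-9) -> float:
    """Shannon entropy H = -sum rho_i ln rho_i with the 0 ln 0 = 0 convention."""
    rho = (dist.densities if isinstance(dist, StrategyDistribution)
           else np.asarray(dist, dtype=float))
    if abs(rho.sum() - 1.0) > atol or np.any(rho < 0):
        raise ValueError("entropy requires a normalized distribution")
    pos = rho[rho > 0]
    return float(-np.sum(pos * np.log(pos)))
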