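"""Synthetic ranked-pair generation by ε-perturbation of an optimal strategy.

Field campaigns rarely observe enough competing strategies to train a
ranking classifier. The workaround implemented here assumes the observed
trajectory ``x*(t)`` is evolutionarily stable (a fitness maximum), so any
deviation ``x*(t) + ε y(t)`` along a fixed periodic direction ``y`` reduces
fitness, and — close to the optimum — a *smaller* ``|ε|`` means *higher*
fitness. Ranked training pairs are therefore only ever formed between
strategies sharing a perturbation direction (or against the unperturbed
base), where the ``|ε|`` comparison defines the label.

Defaults reproduce the study conditions of the unstructured model: 3 random
Fourier directions x 67 signed ε values + the base = 202 strategies, with
the same-direction candidate pairs subsampled to 2031.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentModel
from .feature_space import FitnessCoefficients, RankedPair, fitness_value, lift
from .trajectories import MacroParams, StagePair, Trajectory, macro_params_discrete

__all__ = [
    "Perturbation",
    "Strategy",
    "RankedDataset",
    "make_directions",
    "generate_strategies",
    "label_pairs",
    "split_dataset",
    "default_dataset",
]

BASE_DIRECTION = -1  # direction id of the unperturbed strategy

DEFAULT_N_DIRECTIONS = 3
DEFAULT_MAX_MODE = 3
DEFAULT_EPS_MAX = 20.0  # metres, before any boundary shrinking
DEFAULT_N_EPS = 67
DEFAULT_N_PAIRS = 2031
DEFAULT_TRAIN_FRAC = 0.7


@dataclass(frozen=True)
class Perturbation:
    """A periodic perturbation direction y(t) in truncated Fourier form.

    ``y(t) = a[0] + Σ_m (a[m] cos 2πmt + b[m] sin 2πmt)``, sup-normalized to
    ``max_t |y(t)| = 1`` so that ε carries the physical scale (metres).
    y(0) = y(1) holds by construction.
    """

    direction: int
    a: np.ndarray  # cosine coefficients, index 0 is the constant term
    b: np.ndarray  # sine coefficients (b[0] unused, kept for alignment)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.a[0])
        for m in range(1, self.a.size):
            y = y + self.a[m] * np.cos(2 * np.pi * m * t) \
                  + self.b[m] * np.sin(2 * np.pi * m * t)
        return y

    def scaled(self, factor: float) -> "Perturbation":
        return Perturbation(self.direction, self.a * factor, self.b * factor)


@dataclass(frozen=True)
class Strategy:
    """A candidate strategy with its generation provenance."""

    trajectory: Trajectory | StagePair
    direction: int
    eps: float
    M: MacroParams = field(repr=False, default=None)


@dataclass
class RankedDataset:
    """Strategies, labelled pair differences, and a train/test split."""

    strategies: list[Strategy]
    pairs: list[RankedPair]
    train_idx: np.ndarray
    test_idx: np.ndarray
    n: int
    k: int
    seed: int

    @property
    def train_pairs(self) -> list[RankedPair]:
        return [self.pairs[i] for i in self.train_idx]

    @property
    def test_pairs(self) -> list[RankedPair]:
        return [self.pairs[i] for i in self.test_idx]


def _sup_norm(p: Perturbation, grid: int = 512) -> float:
    t = np.arange(grid) / grid
    return float(np.max(np.abs(p(t))))


def make_directions(n_dirs: int, max_mode: int = DEFAULT_MAX_MODE,
                    seed: int = 0) -> list[Perturbation]:
    """Seeded random Fourier directions, each sup-normalized to 1."""
    if n_dirs < 1 or max_mode < 1:
        raise ValueError("need n_dirs >= 1 and max_mode >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n_dirs):
        a = rng.normal(size=max_mode + 1)
        b = rng.normal(size=max_mode + 1)
        b[0] = 0.0
        p = Perturbation(d, a, b)
        out.append(p.scaled(1.0 / _sup_norm(p)))
    return out


def _fit_direction_to_domain(base: Trajectory, p: Perturbation,
                             eps_max: float, env: EnvironmentModel,
                             buffer: float = 1.0) -> Perturbation:
    """Shrink a direction so base + ε·y stays inside the column for |ε| ≤ eps_max.

    Shrinking preserves every same-direction ranking (it only rescales the
    physical step per unit ε along that direction).
    """
    t, x = base.times, base.samples
    y = p(t)
    headroom_up = -x - buffer            # distance to the surface
    headroom_down = x + env.C - buffer   # distance to the bottom
    with np.errstate(divide="ignore"):
        limit = np.minimum(
            np.where(np.abs(y) > 0, headroom_up / (eps_max * np.abs(y)), np.inf),
            np.where(np.abs(y) > 0, headroom_down / (eps_max * np.abs(y)), np.inf),
        )
    factor = min(1.0, float(np.min(limit)))
    if factor <= 0:
        raise RuntimeError("base trajectory leaves no room for perturbations")
    return p if factor >= 1.0 else p.scaled(factor)


def default_eps_grid(eps_max: float = DEFAULT_EPS_MAX,
                     n_eps: int = DEFAULT_N_EPS,
                     eps_min: float = 0.5) -> np.ndarray:
    """Signed ε grid: ceil(n/2) positive magnitudes and their negatives.

    For the default n_eps=67 this yields 34 positive and 33 negative values,
    so each of 3 directions contributes 67 strategies and the base brings the
    total to the study's 202.
    """
    n_pos = (n_eps + 1) // 2
    mags = np.linspace(eps_min, eps_max, n_pos)
    return np.concatenate([mags, -mags[: n_eps - n_pos]])


def generate_strategies(base: Trajectory | StagePair,
                        directions: list[Perturbation],
                        eps_grid: np.ndarray,
                        env: EnvironmentModel,
                        adult_directions: list[Perturbation] | None = None,
                        ) -> list[Strategy]:
    """Perturbed strategies base + ε·y for every retained (direction, ε).

    The unperturbed base is always included once (direction id -1, ε=0).
    Candidates leaving the column domain are rejected. For a two-stage base,
    ``adult_directions`` perturbs the adult path (juvenile uses
    ``directions``) with the shared ε, so the one-dimensional |ε| ranking
    still applies.
    """
    two_stage = isinstance(base, StagePair)
    if two_stage and adult_directions is None:
        raise ValueError("two-stage generation needs adult_directions")

    def perturbed(eps: float, d: int) -> Trajectory | StagePair | None:
        if two_stage:
            juv = base.juvenile.samples + eps * directions[d](base.juvenile.times)
            adu = base.adult.samples + eps * adult_directions[d](base.adult.times)
            if _out_of_domain(juv, env) or _out_of_domain(adu, env):
                return None
            return StagePair(Trajectory(juv, "juvenile"), Trajectory(adu, "adult"))
        x = base.samples + eps * directions[d](base.times)
        if _out_of_domain(x, env):
            return None
        return Trajectory(x, base.stage)

    strategies = [Strategy(base, BASE_DIRECTION, 0.0,
                           macro_params_discrete(base, env))]
    n_rejected = 0
    for d in range(len(directions)):
        for eps in eps_grid:
            if eps == 0.0:
                continue  # the base is already present once
            traj = perturbed(float(eps), d)
            if traj is None:
                n_rejected += 1
                continue
            strategies.append(
                Strategy(traj, d, float(eps), macro_params_discrete(traj, env)))
    if len(strategies) <= 1 and n_rejected > 0:
        raise RuntimeError(
            f"all {n_rejected} perturbation candidates left the column domain")
    return strategies


def _out_of_domain(x: np.ndarray, env: EnvironmentModel) -> bool:
    return bool(np.any((x > 0.0) | (x <= -env.C)))


def label_pairs(strategies: list[Strategy], k: int,
                policy: str = "same-direction",
                oracle: FitnessCoefficients | None = None,
                max_pairs: int | None = None,
                seed: int = 0) -> list[RankedPair]:
    """Labelled pair-difference vectors from a strategy collection.

    policy "same-direction": compare only strategies sharing a perturbation
    direction (the base compares with everything); the smaller ``|ε|`` is
    the fitter one; ties ``|ε_v| = |ε_w|`` are skipped. policy "oracle":
    all pairs, labelled by the supplied true fitness (validation studies).
    Pair orientation is randomized (seeded) so labels are balanced; if
    ``max_pairs`` is given the candidate list is subsampled to that size.
    """
    if policy not in ("same-direction", "oracle"):
        raise ValueError(f"unknown pair-labelling policy {policy!r}")
    if policy == "oracle" and oracle is None:
        raise ValueError("oracle policy requires a fitness-coefficient oracle")
    rng = np.random.default_rng(seed)
    n = strategies[0].M.n
    candidates: list[tuple[int, int]] = []
    for i in range(len(strategies)):
        for j in range(i + 1, len(strategies)):
            si, sj = strategies[i], strategies[j]
            if policy == "same-direction":
                same = (si.direction == sj.direction
                        or si.direction == BASE_DIRECTION
                        or sj.direction == BASE_DIRECTION)
                if not same or abs(si.eps) == abs(sj.eps):
                    continue
            candidates.append((i, j))
    if max_pairs is not None and max_pairs < len(candidates):
        keep = rng.choice(len(candidates), size=max_pairs, replace=False)
        candidates = [candidates[i] for i in sorted(keep)]

    pairs: list[RankedPair] = []
    for i, j in candidates:
        si, sj = strategies[i], strategies[j]
        if policy == "same-direction":
            better_first = abs(si.eps) < abs(sj.eps)
        else:
            fi = fitness_value(si.M, oracle)
            fj = fitness_value(sj.M, oracle)
            if fi == fj:
                continue
            better_first = fi > fj
        v, w = (si, sj) if better_first else (sj, si)
        diff = lift(v.M, k) - lift(w.M, k)
        label = 1
        if rng.random() < 0.5:  # balance the labels
            diff, label = -diff, -1
            v, w = w, v
        pairs.append(RankedPair(diff, label, direction=v.direction,
                                eps_v=v.eps, eps_w=w.eps))
    return pairs


def split_dataset(pairs: list[RankedPair], train_frac: float = DEFAULT_TRAIN_FRAC,
                  seed: int = 0, n: int = 4, k: int = 1,
                  strategies: list[Strategy] | None = None) -> RankedDataset:
    """Seeded random train/test split at the pair level."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_train = int(np.floor(train_frac * len(pairs) + 0.5))
    n_train = min(max(n_train, 1), len(pairs) - 1)
    return RankedDataset(strategies or [], pairs,
                         train_idx=np.sort(perm[:n_train]),
                         test_idx=np.sort(perm[n_train:]),
                         n=n, k=k, seed=seed)


def default_dataset(env: EnvironmentModel, base: Trajectory,
                    seed: int = 0, k: int = 1,
                    n_dirs: int = DEFAULT_N_DIRECTIONS,
                    max_mode: int = DEFAULT_MAX_MODE,
                    eps_max: float = DEFAULT_EPS_MAX,
                    n_eps: int = DEFAULT_N_EPS,
                    n_pairs: int = DEFAULT_N_PAIRS,
                    train_frac: float = DEFAULT_TRAIN_FRAC) -> RankedDataset:
    """The study-default ranked dataset: 202 strategies, 2031 labelled pairs.

    Directions are shrunk where needed so every ε in the grid stays inside
    the water column (rescaling a direction preserves all its rankings), so
    the strategy count is exactly ``n_dirs * n_eps + 1``.
    """
    directions = [
        _fit_direction_to_domain(base, p, eps_max, env)
        for p in make_directions(n_dirs, max_mode, seed)
    ]
    strategies = generate_strategies(base, directions, default_eps_grid(eps_max, n_eps), env)
    pairs = label_pairs(strategies, k, "same-direction",
                        max_pairs=n_pairs, seed=seed)
    return split_dataset(pairs, train_frac, seed, n=strategies[0].M.n, k=k,
                         strategies=strategies)
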