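"""Analytic verification of a reconstructed two-stage fitness.

An independent check of the data-driven quadratic fitness: a classical
two-stage demographic model (juveniles n_j, adults n_a) with maturation p,
juvenile mortality q, reproduction r, adult mortality s and a shared
intraspecific-competition mortality c*N,

    dn_j/dt = r*n_a - (p + q)*n_j - c*n_j*(n_j + n_a)
    dn_a/dt = p*n_j - s*n_a   - c*n_a*(n_j + n_a),

has an analytic invasion fitness: the leading eigenvalue of the linear part
(the shared competition term shifts every strategy's growth rate equally
and cancels from any ranking). Demographic rates are tied to the trajectory
macro-parameters by a positive-weighted linear change of variables
(p, q from the juvenile M1..M4; r, s from the adult M5..M8), which lets the
machine-learned quadratic coefficients over M be re-expressed as Taylor
coefficients h_i, h_ij over (p, q, r, s) and compared, term by term, with
the Taylor expansion of the eigenvalue fitness around a demographic point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .fitness_optima import QuadraticFitnessCoeffs
from .trajectories import MacroParams

__all__ = [
    "StageParams",
    "WeightMap",
    "HCoefficients",
    "stage_model_rhs",
    "analytic_fitness",
    "pqrs_from_M",
    "taylor_h",
    "h_w_to_lambda",
    "lambda_to_h",
    "compare_coefficients",
]

_PQRS = ("p", "q", "r", "s")

# macro-parameter slots (0-based) feeding each demographic rate
_P_SLOTS = (0, 2, 3)   # M1, M3, M4 with weights theta1, phi1, psi1
_Q_SLOT = 1            # M2 with weight zeta1
_R_SLOTS = (4, 6, 7)   # M5, M7, M8 with weights theta2, phi2, psi2
_S_SLOT = 5            # M6 with weight zeta2


@dataclass(frozen=True)
class StageParams:
    """Demographic rates (per day): maturation p, juvenile mortality q,
    reproduction r, adult mortality s."""

    p: float
    q: float
    r: float
    s: float

    def __post_init__(self) -> None:
        for name in _PQRS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.q, self.r, self.s])


@dataclass(frozen=True)
class WeightMap:
    """Positive weights of the M -> (p, q, r, s) change of variables."""

    theta1: float
    phi1: float
    psi1: float
    zeta1: float
    theta2: float
    phi2: float
    psi2: float
    zeta2: float

    def __post_init__(self) -> None:
        for name in ("theta1", "phi1", "psi1", "zeta1",
                     "theta2", "phi2", "psi2", "zeta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"weight {name} must be > 0")

    def group_vectors(self) -> np.ndarray:
        """Rows: gradient of p, q, r, s w.r.t. the 8-vector M."""
        G = np.zeros((4, 8))
        G[0, list(_P_SLOTS)] = (self.theta1, self.phi1, self.psi1)
        G[1, _Q_SLOT] = self.zeta1
        G[2, list(_R_SLOTS)] = (self.theta2, self.phi2, self.psi2)
        G[3, _S_SLOT] = self.zeta2
        return G


@dataclass(frozen=True)
class HCoefficients:
    """Taylor coefficients of fitness in (p, q, r, s): linear h_i and
    symmetric quadratic h_ij stored once (upper triangle)."""

    linear: np.ndarray      # shape (4,)
    quadratic: np.ndarray   # shape (4, 4), upper triangle meaningful
    normalization: str = "raw"

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float)
        quad = np.triu(np.asarray(self.quadratic, dtype=float))
        if lin.shape != (4,) or quad.shape != (4, 4):
            raise ValueError("need linear shape (4,) and quadratic shape (4, 4)")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "quadratic", quad)

    def normalized_r1(self) -> "HCoefficients":
        """Rescale so the linear reproduction coefficient h3 equals 1."""
        h3 = self.linear[2]
        if h3 == 0:
            raise ZeroDivisionError("cannot normalize: h3 (the r coefficient) is 0")
        return HCoefficients(self.linear / h3, self.quadratic / h3, "r=1")

    def named(self) -> dict[str, float]:
        out = {f"h{i + 1}": float(self.linear[i]) for i in range(4)}
        for i in range(4):
            for j in range(i, 4):
                out[f"h{i + 1}{j + 1}"] = float(self.quadratic[i, j])
        return out


def stage_model_rhs(n_j: float, n_a: float, params: StageParams,
                    c: float = 0.0) -> tuple[float, float]:
    """Right-hand side of the two-stage competition model."""
    if n_j < 0 or n_a < 0:
        raise ValueError(f"densities must be >= 0, got ({n_j}, {n_a})")
    N = n_j + n_a
    dj = params.r * n_a - (params.p + params.q) * n_j - c * n_j * N
    da = params.p * n_j - params.s * n_a - c * n_a * N
    return dj, da


def analytic_fitness(params: StageParams) -> float:
    """Invasion fitness: leading eigenvalue of [[-(p+q), r], [p, -s]].

    lambda_+ = (-(p+q+s) + sqrt((p+q-s)^2 + 4 p r)) / 2.
    """
    p, q, r, s = params.p, params.q, params.r, params.s
    disc = (p + q - s) ** 2 + 4.0 * p * r
    return 0.5 * (-(p + q + s) + np.sqrt(disc))


def pqrs_from_M(M: MacroParams | np.ndarray, w: WeightMap) -> StageParams:
    """Demographic rates from macro-parameters via the weighted linear map.

    Because M2, M3, M4 (and M6..M8) are non-positive by convention while the
    weights are positive, a combination can come out negative; biological
    rates are clamped at 0 with a warning.
    """
    m = M.values if isinstance(M, MacroParams) else np.asarray(M, dtype=float)
    if m.shape != (8,):
        raise ValueError(f"need an 8-vector of macro-parameters, got {m.shape}")
    raw = w.group_vectors() @ m
    if np.any(raw < 0):
        neg = [name for name, v in zip(_PQRS, raw) if v < 0]
        warnings.warn(f"negative rate(s) {neg} clamped to 0", stacklevel=2)
    raw = np.maximum(raw, 0.0)
    return StageParams(*raw)


def taylor_h(fitness: Callable[[StageParams], float], point: StageParams,
             step: float = 1e-5, convention: str | None = None) -> HCoefficients:
    """Second-order Taylor coefficients of a fitness at a demographic point.

    Central finite differences with per-coordinate step ``step * max(|x_i|, 1)``.
    The returned quadratic entries are Taylor coefficients (h_ii multiplies
    x_i^2, h_ij with i<j multiplies x_i*x_j once). ``convention="r=1"``
    rescales so the linear r coefficient is 1.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    x0 = point.as_array()
    hsteps = step * np.maximum(np.abs(x0), 1.0)

    def f(x: np.ndarray) -> float:
        return float(fitness(StageParams(*np.maximum(x, 0.0))))

    f0 = f(x0)
    lin = np.zeros(4)
    quad = np.zeros((4, 4))
    for i in range(4):
        ei = np.zeros(4)
        ei[i] = hsteps[i]
        fp, fm = f(x0 + ei), f(x0 - ei)
        lin[i] = (fp - fm) / (2 * hsteps[i])
        quad[i, i] = (fp - 2 * f0 + fm) / (2 * hsteps[i] ** 2)  # coeff of x_i^2
    for i in range(4):
        for j in range(i + 1, 4):
            ei = np.zeros(4)
            ej = np.zeros(4)
            ei[i], ej[j] = hsteps[i], hsteps[j]
            fpp, fpm = f(x0 + ei + ej), f(x0 + ei - ej)
            fmp, fmm = f(x0 - ei + ej), f(x0 - ei - ej)
            quad[i, j] = (fpp - fpm - fmp + fmm) / (4 * hsteps[i] * hsteps[j])
    if not np.all(np.isfinite(lin)) or not np.all(np.isfinite(quad)):
        raise ArithmeticError("non-finite finite-difference coefficients")
    out = HCoefficients(lin, quad)
    return out.normalized_r1() if convention == "r=1" else out


def h_w_to_lambda(h: HCoefficients, w: WeightMap) -> QuadraticFitnessCoeffs:
    """Forward expansion: substitute the M -> (p,q,r,s) map into the h-form.

    Yields the quadratic fitness coefficients over M (linear lam_i and
    stored-once lam_ij) that the ranking classifier would estimate.
    """
    G = w.group_vectors()
    linear = G.T @ h.linear
    # symmetric group-level quadratic form: diagonal h_ii, off-diagonal h_ij/2
    H = np.triu(h.quadratic)
    Hs = 0.5 * (H + H.T)
    S = G.T @ Hs @ G  # symmetric 8x8 over M
    quad = np.triu(2.0 * S) - np.diag(np.diag(S))  # stored-once convention
    return QuadraticFitnessCoeffs(linear, quad)


def lambda_to_h(lam: QuadraticFitnessCoeffs,
                fixed_h: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
                tol: float = 1e-8):
    """Invert the substitution: recover (h, w) from quadratic M-coefficients.

    With the four linear coefficients h1..h4 fixed, the eight weights follow
    uniquely from the linear terms; every quadratic h_ij is then
    over-determined by monomial ratios, whose spread is reported as a
    residual. Returns ``(HCoefficients, WeightMap, residuals: dict)``.
    """
    h1, h2, h3, h4 = fixed_h
    if 0.0 in (h1, h2, h3, h4):
        raise ZeroDivisionError("fixed h1..h4 must be nonzero")
    lin = lam.linear
    w = WeightMap(
        theta1=lin[_P_SLOTS[0]] / h1, phi1=lin[_P_SLOTS[1]] / h1,
        psi1=lin[_P_SLOTS[2]] / h1, zeta1=lin[_Q_SLOT] / h2,
        theta2=lin[_R_SLOTS[0]] / h3, phi2=lin[_R_SLOTS[1]] / h3,
        psi2=lin[_R_SLOTS[2]] / h3, zeta2=lin[_S_SLOT] / h4,
    )
    G = w.group_vectors()
    Q = np.triu(lam.quadratic)

    groups = [list(_P_SLOTS), [_Q_SLOT], list(_R_SLOTS), [_S_SLOT]]
    quad = np.zeros((4, 4))
    residuals: dict[str, float] = {}
    for a in range(4):
        for b in range(a, 4):
            cands = []
            for i in groups[a]:
                for j in groups[b]:
                    if a == b and i > j:
                        continue
                    lo_idx, hi_idx = min(i, j), max(i, j)
                    coeff = Q[lo_idx, hi_idx]
                    if a == b:
                        denom = G[a, i] * G[a, j] * (1.0 if i == j else 2.0)
                    else:
                        denom = G[a, i] * G[b, j]
                    if denom != 0:
                        cands.append(coeff / denom)
            est = float(np.mean(cands))
            quad[a, b] = est
            spread = float(np.max(np.abs(np.asarray(cands) - est))) if cands else 0.0
            residuals[f"h{a + 1}{b + 1}"] = spread
    worst = max(residuals.values())
    scale = max(1.0, float(np.max(np.abs(quad))))
    if worst > tol * scale:
        residuals["consistent"] = False
    else:
        residuals["consistent"] = True
    h = HCoefficients(np.array(fixed_h), quad)
    return h, w, residuals


_NAME_ORDER = ["h1", "h2", "h3", "h4",
               "h11", "h22", "h33", "h44",
               "h12", "h13", "h14", "h23", "h24", "h34"]


def compare_coefficients(h_model: HCoefficients,
                         h_reconstructed: HCoefficients) -> pd.DataFrame:
    """Side-by-side coefficient table (analytic vs reconstructed).

    Both inputs must be in the same normalization gauge. Rows carry absolute
    and relative differences and a sign-disagreement flag.
    """
    if h_model.normalization != h_reconstructed.normalization:
        raise ValueError(
            f"normalization mismatch: {h_model.normalization!r} vs "
            f"{h_reconstructed.normalization!r}")
    a, b = h_model.named(), h_reconstructed.named()
    rows = []
    for name in _NAME_ORDER:
        va, vb = a[name], b[name]
        denom = max(abs(va), abs(vb))
        rows.append({
            "coefficient": name,
            "analytic": va,
            "reconstructed": vb,
            "abs_diff": abs(va - vb),
            "rel_diff": abs(va - vb) / denom if denom > 0 else 0.0,
            "sign_flip": bool(va * vb < 0),
        })
    return pd.DataFrame(rows)
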