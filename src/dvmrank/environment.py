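"""Parameterized water-column environments for the DVM fitness model.

Two profile families are supported, both defined on the column
``-C < x <= 0`` (``x`` is the signed depth in metres, negative below the
surface):

* **lin-quad** — food and predator density grow linearly with height above
  the bottom, ``E = sigma1*(x + C)``, ``Sx = sigma2*(x + C)``, and the
  unfavourable-depth mortality is a parabola ``G = (x + C0)**2`` centred at
  the preferred depth ``-C0``.
* **hyperbolic** — sigmoidal food/predator profiles
  ``E = sigma1*(tanh(xi1*(x + C1)) + 1)`` (likewise ``Sx``) with a
  thermocline-like centre at ``-C1``, and ``G = cosh(xi3*(x + C0))``.

In both families the diel activity of visual predators is
``St(t) = cos(2*pi*t) + 1`` with ``t`` the day fraction (t=0 midnight),
so predation risk is the separable product ``St(t) * Sx(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Union

import numpy as np
import yaml

__all__ = [
    "LinQuadEnv",
    "HyperbolicEnv",
    "EnvironmentModel",
    "eval_profiles",
    "default_env",
    "load_env",
]


class DomainError(ValueError):
    """A depth or time coordinate falls outside the model domain."""


class ConfigurationError(ValueError):
    """An environment configuration is malformed or unsupported."""


@dataclass(frozen=True)
class LinQuadEnv:
    """Linear food/predation profiles with quadratic depth mortality.

    Parameters
    ----------
    sigma1 : float
        Food-density slope (food units per metre of height above ``-C``).
    sigma2 : float
        Predator-density slope (per metre).
    C : float
        Water-column depth scale in metres; the domain is ``-C < x <= 0``.
    C0 : float
        Centre of the preferred depth band, metres (mortality minimum
        at ``x = -C0``).
    """

    sigma1: float = 0.25
    sigma2: float = 0.003
    C: float = 140.0
    C0: float = 60.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be > 0")

    def E(self, x):
        return self.sigma1 * (np.asarray(x) + self.C)

    def Sx(self, x):
        return self.sigma2 * (np.asarray(x) + self.C)

    def G(self, x):
        return (np.asarray(x) + self.C0) ** 2


@dataclass(frozen=True)
class HyperbolicEnv:
    """Sigmoidal food/predation profiles with cosh depth mortality."""

    sigma1: float = 0.25
    sigma2: float = 0.003
    C: float = 140.0
    C0: float = 80.0
    C1: float = 40.0
    xi1: float = 0.025
    xi2: float = 0.025
    xi3: float = 0.2

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be > 0")

    def E(self, x):
        return self.sigma1 * (np.tanh(self.xi1 * (np.asarray(x) + self.C1)) + 1.0)

    def Sx(self, x):
        return self.sigma2 * (np.tanh(self.xi2 * (np.asarray(x) + self.C1)) + 1.0)

    def G(self, x):
        return np.cosh(self.xi3 * (np.asarray(x) + self.C0))


EnvParams = Union[LinQuadEnv, HyperbolicEnv]

_FAMILIES = {"lin-quad": LinQuadEnv, "hyperbolic": HyperbolicEnv}


@dataclass(frozen=True)
class EnvironmentModel:
    """A tagged environment: family name plus its parameter record."""

    family: str
    params: EnvParams

    def __post_init__(self) -> None:
        cls = _FAMILIES.get(self.family)
        if cls is None:
            raise ConfigurationError(
                f"unknown environment family {self.family!r}; "
                f"expected one of {sorted(_FAMILIES)}"
            )
        if not isinstance(self.params, cls):
            raise ConfigurationError(
                f"family {self.family!r} requires {cls.__name__} parameters"
            )

    @property
    def C(self) -> float:
        return self.params.C

    def St(self, t):
        """Diel predator activity, cos(2*pi*t) + 1; unit mean over a day."""
        return np.cos(2.0 * np.pi * np.asarray(t)) + 1.0

    def check_domain(self, x) -> None:
        x = np.asarray(x, dtype=float)
        bad = (x > 0.0) | (x <= -self.params.C)
        if np.any(bad):
            idx = int(np.argmax(bad))
            val = float(np.atleast_1d(x).ravel()[idx])
            raise DomainError(
                f"depth x={val:g} m outside the column (-{self.params.C:g}, 0] "
                f"at sample index {idx}"
            )


def eval_profiles(env: EnvironmentModel, x, t):
    """Evaluate the four environmental profiles at depth ``x``, time ``t``.

    Returns ``(E, Sx, St, G)``. ``St`` depends only on ``t``; the other three
    only on ``x``. Raises :class:`DomainError` if ``x`` leaves ``(-C, 0]``.
    """
    env.check_domain(x)
    p = env.params
    return p.E(x), p.Sx(x), env.St(t), p.G(x)


def default_env(family: str) -> EnvironmentModel:
    """Environment with the study's default parameters for ``family``.

    ``"lin-quad"``: C=140 m, C0=60 m, sigma1=0.25, sigma2=0.003.
    ``"hyperbolic"``: C=140 m, C0=80 m, C1=40 m, same sigmas,
    xi1=xi2=0.025 /m, xi3=0.2 /m.
    """
    cls = _FAMILIES.get(family)
    if cls is None:
        raise ConfigurationError(
            f"unknown environment family {family!r}; expected one of "
            f"{sorted(_FAMILIES)}"
        )
    return EnvironmentModel(family=family, params=cls())


def load_env(path) -> EnvironmentModel:
    """Read an environment from a YAML/JSON config file.

    Keys: ``family`` plus any parameter overrides (``sigma1``, ``sigma2``,
    ``C``, ``C0`` and, for the hyperbolic family, ``C1``, ``xi1``, ``xi2``,
    ``xi3``).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "family" not in cfg:
        raise ConfigurationError(f"environment file {path} lacks a 'family' key")
    family = cfg.pop("family")
    cls = _FAMILIES.get(family)
    if cls is None:
        raise ConfigurationError(f"unknown environment family {family!r} in {path}")
    valid = {f.name for f in fields(cls)}
    unknown = set(cfg) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown parameter(s) {sorted(unknown)} for family {family!r}"
        )
    return EnvironmentModel(family=family, params=cls(**cfg))
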