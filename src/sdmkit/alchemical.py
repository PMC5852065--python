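"""Alchemical state definitions and the lambda/temperature-coupled potential.

The single-decoupling scheme computes an absolute binding free energy along a
nonphysical path in which the ligand-receptor interaction energy ``u`` is
scaled by a coupling parameter ``lambda`` in [0, 1].  The reduced (thermal
units) effective potential of a configuration with decoupled-state energy
``u0`` and binding energy ``u`` in the thermodynamic state ``(lambda, T)`` is

    U_lambda(r) = beta * [u0(r) + lambda * u'(r)],    beta = 1 / (kB T)

where ``u'`` is the soft-core capped binding energy.  The cap bounds large
positive binding energies (near-overlapping configurations sampled at small
lambda) at ``u_max`` through a smooth tanh saturation while leaving favorable
(negative) energies untouched.

Free energies are in kcal/mol throughout; ``kb=1`` switches any routine to
dimensionless units for toy tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KB",
    "STANDARD_VOLUME",
    "DEFAULT_UMAX",
    "DEFAULT_LAMBDAS",
    "AlchemicalState",
    "StateGrid",
    "BindingSite",
    "EnergyPair",
    "softcore_transform",
    "reduced_potential",
    "standard_state_correction",
    "flat_bottom_restraint",
    "sphere_site_volume",
    "default_temperature_ladder",
]

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872

#: Volume per molecule at the 1 M standard concentration, Angstrom^3.
#: Encoded as the printed constant (1 M == one molecule per 1668 A^3).
STANDARD_VOLUME = 1668.0

#: Default soft-core cap, kcal/mol.
DEFAULT_UMAX = 1000.0

#: The 26-step coupling schedule used for the production runs this toolkit
#: emulates: dense near lambda = 0 where the soft-core cap dominates, coarser
#: toward full coupling.
DEFAULT_LAMBDAS: tuple[float, ...] = (
    0.0, 0.002, 0.0048, 0.006, 0.008, 0.01, 0.015, 0.02, 0.0225, 0.025,
    0.03, 0.0325, 0.035, 0.04, 0.07, 0.1, 0.25, 0.35, 0.45, 0.55,
    0.65, 0.71, 0.78, 0.85, 0.92, 1.0,
)


class InvalidInputError(ValueError):
    """Raised for non-finite or out-of-contract numeric inputs."""


@dataclass(frozen=True)
class AlchemicalState:
    """One (lambda, temperature) thermodynamic state.

    ``beta`` is derived from the temperature so the two can never drift
    apart.  ``kb`` defaults to kcal/mol/K units; pass ``kb=1.0`` for
    dimensionless toy problems.
    """

    lam: float
    temperature: float
    kb: float = KB

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise InvalidInputError(f"lambda must be in [0, 1], got {self.lam}")
        if not self.temperature > 0:
            raise InvalidInputError(
                f"temperature must be positive, got {self.temperature}"
            )

    @property
    def beta(self) -> float:
        return 1.0 / (self.kb * self.temperature)


@dataclass(frozen=True)
class StateGrid:
    """The 2-D ladder of alchemical states: a cross product of coupling
    values and temperatures.

    The state with flattened index ``k`` is
    ``(lambdas[k % n_lambda], temperatures[k // n_lambda])``: lambda varies
    fastest.  The coupling schedule must start at 0 (decoupled) and end at 1
    (fully coupled) so that both endpoint ensembles exist.
    """

    lambdas: tuple[float, ...]
    temperatures: tuple[float, ...]
    kb: float = KB

    def __init__(
        self,
        lambdas: Sequence[float],
        temperatures: Sequence[float],
        kb: float = KB,
    ) -> None:
        lams = tuple(float(x) for x in lambdas)
        temps = tuple(float(x) for x in temperatures)
        if len(lams) < 1 or len(temps) < 1:
            raise InvalidInputError("grid needs at least one lambda and one temperature")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise InvalidInputError("lambdas must be strictly increasing")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise InvalidInputError("lambda schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise InvalidInputError("temperatures must be strictly increasing")
        if any(t <= 0 for t in temps):
            raise InvalidInputError("temperatures must be positive")
        object.__setattr__(self, "lambdas", lams)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "kb", float(kb))

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    @property
    def n_temperature(self) -> int:
        return len(self.temperatures)

    @property
    def n_states(self) -> int:
        return self.n_lambda * self.n_temperature

    def __len__(self) -> int:
        return self.n_states

    @property
    def states(self) -> list[AlchemicalState]:
        return [
            AlchemicalState(lam, t, self.kb)
            for t in self.temperatures
            for lam in self.lambdas
        ]

    def state(self, k: int) -> AlchemicalState:
        it, il = divmod(int(k), self.n_lambda)
        return AlchemicalState(self.lambdas[il], self.temperatures[it], self.kb)

    def flat_index(self, i_temperature: int, i_lambda: int) -> int:
        return i_temperature * self.n_lambda + i_lambda

    def unravel(self, k: int) -> tuple[int, int]:
        """Flattened state index -> (temperature index, lambda index)."""
        return divmod(int(k), self.n_lambda)

    def index_of(self, lam: float, temperature: float, atol: float = 1e-9) -> int:
        """Flattened index of the state matching (lam, temperature)."""
        for il, lv in enumerate(self.lambdas):
            if abs(lv - lam) <= atol:
                for it, tv in enumerate(self.temperatures):
                    if abs(tv - temperature) <= atol:
                        return self.flat_index(it, il)
        raise KeyError(f"state (lambda={lam}, T={temperature}) not in grid")

    def lam_of_states(self) -> np.ndarray:
        """Per-state lambda values, shape (n_states,)."""
        return np.tile(np.asarray(self.lambdas), self.n_temperature)

    def beta_of_states(self) -> np.ndarray:
        """Per-state inverse temperatures, shape (n_states,)."""
        return np.repeat(1.0 / (self.kb * np.asarray(self.temperatures)), self.n_lambda)

    def to_dict(self) -> dict:
        return {
            "lambdas": list(self.lambdas),
            "temperatures": list(self.temperatures),
            "kb": self.kb,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateGrid":
        return cls(d["lambdas"], d["temperatures"], d.get("kb", KB))


def default_temperature_ladder(
    n: int = 8, t_min: float = 300.0, t_max: float = 379.0
) -> tuple[float, ...]:
    """Geometrically spaced temperature ladder (equal beta-ratio steps).

    The production runs used eight temperatures spanning 300-379 K; only the
    endpoints are fixed here, the geometric interior spacing is this
    package's choice (it equalizes nearest-neighbor exchange overlap for
    energy distributions of roughly constant relative width).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if n == 1:
        return (float(t_min),)
    ratio = (t_max / t_min) ** (1.0 / (n - 1))
    temps = [t_min * ratio**i for i in range(n)]
    temps[-1] = float(t_max)  # exact endpoint despite rounding
    return tuple(temps)


@dataclass(frozen=True)
class BindingSite:
    """Flat-bottom spherical binding-site definition.

    The ligand reference point (its position in the toy models; a center of
    mass in molecular applications) feels no restraint within ``radius`` of
    the site center and a harmonic penalty ``force_constant * (d - radius)^2``
    beyond it.  ``volume`` is the site volume entering the standard-state
    correction; by default the sphere volume of ``radius``.
    """

    radius: float
    force_constant: float = 3.0
    center_rule: str = "receptor origin"
    volume: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidInputError(f"site radius must be positive, got {self.radius}")
        if self.force_constant < 0:
            raise InvalidInputError("force constant must be non-negative")
        if self.volume == 0.0:
            object.__setattr__(self, "volume", sphere_site_volume(self.radius))
        if not self.volume > 0:
            raise InvalidInputError(f"site volume must be positive, got {self.volume}")


@dataclass(frozen=True)
class EnergyPair:
    """Decoupled-state effective energy ``u0`` and binding energy ``u``
    (both kcal/mol) for one configuration."""

    u0: float
    u: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u0) and np.isfinite(self.u)):
            raise InvalidInputError(f"energies must be finite, got {self.u0}, {self.u}")


def softcore_transform(u, u_max: float = DEFAULT_UMAX):
    """Soft-core cap on the binding energy.

    Identity for u <= 0; ``u_max * tanh(u / u_max)`` for u > 0, so the output
    is bounded above by ``u_max``, globally 1-Lipschitz, monotone, and C^1 at
    u = 0.  Accepts scalars or arrays.
    """
    if not u_max > 0:
        raise InvalidInputError(f"u_max must be positive, got {u_max}")
    u_arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_arr)):
        raise InvalidInputError("binding energy must be finite")
    out = np.where(u_arr > 0, u_max * np.tanh(u_arr / u_max), u_arr)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(out)
    return out


def reduced_potential(pair, state: AlchemicalState, u_max: float = DEFAULT_UMAX):
    """Dimensionless lambda/temperature-coupled effective potential.

    ``beta * (u0 + lambda * softcore(u, u_max))``.  ``pair`` may be an
    :class:`EnergyPair` or a ``(u0, u)`` tuple of scalars/arrays.  Exactly
    linear in lambda at a fixed configuration; reduces to ``beta * u0`` at
    lambda = 0.
    """
    if isinstance(pair, EnergyPair):
        u0, u = pair.u0, pair.u
    else:
        u0, u = pair
    u0_arr = np.asarray(u0, dtype=float)
    if not np.all(np.isfinite(u0_arr)):
        raise InvalidInputError("decoupled energy must be finite")
    val = state.beta * (u0_arr + state.lam * np.asarray(softcore_transform(u, u_max)))
    if np.ndim(val) == 0:
        return float(val)
    return val


def standard_state_correction(
    v_site: float, temperature: float, kb: float = KB
) -> float:
    """Concentration term converting the site-restricted excess binding free
    energy to the 1 M standard state: ``-kB T ln(C* V_site)`` with
    ``C* = 1/1668 A^-3``.

    Zero when the site volume equals 1668 A^3; positive for smaller sites.
    """
    if not v_site > 0:
        raise InvalidInputError(f"site volume must be positive, got {v_site}")
    if not temperature > 0:
        raise InvalidInputError(f"temperature must be positive, got {temperature}")
    return -kb * temperature * math.log(v_site / STANDARD_VOLUME)


def flat_bottom_restraint(distance, site: BindingSite, half: bool = False):
    """Flat-bottom harmonic site restraint energy, kcal/mol.

    Zero inside ``site.radius``; ``k (d - r)^2`` beyond it (continuous at the
    boundary).  Whether the conventional 1/2 belongs in front of a "force
    constant of k kcal/mol/A^2" is ambiguous in the literature; the default
    here omits it, ``half=True`` includes it.  Accepts scalars or arrays.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("distance must be non-negative")
    excess = np.clip(d - site.radius, 0.0, None)
    k = 0.5 * site.force_constant if half else site.force_constant
    out = k * excess**2
    if np.isscalar(distance) or d.ndim == 0:
        return float(out)
    return out


def sphere_site_volume(radius: float) -> float:
    """Volume of a spherical site, (4/3) pi r^3, Angstrom^3."""
    if not radius > 0:
        raise InvalidInputError(f"radius must be positive, got {radius}")
    return 4.0 / 3.0 * math.pi * radius**3
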