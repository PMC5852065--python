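"""Thermodynamic decomposition of the binding free energy.

The standard binding free energy splits into the mean binding energy and a
reorganization term,

    dG_reorg = dG_b(std) - dE_b,

where dE_b is the average ligand-receptor interaction energy in the fully
coupled ensemble.  Running the estimator at every temperature of the ladder
gives dG_b(std)(T); its slope is minus the binding entropy,
dS_b = -d(dG_b)/dT, obtained by weighted linear least squares with the
per-temperature Fisher sigmas as weights.  The reorganization free energy
then further decomposes into an energetic strain term and the entropic
penalty,

    dE_reorg = dG_reorg - (-T dS_b),

so that dG_reorg = dE_reorg + penalty exactly (closure identity).  The
entropic penalty -T dS_b is positive when binding confines the ligand.
All reported uncertainties are twice the standard deviation; internal
sigmas are 1-sigma and doubled at assembly time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alchemical import DEFAULT_UMAX, InvalidInputError, StateGrid
from .sampler import SampleSet
from . import diagnostics as _diag
from . import uwham as _uwham

__all__ = [
    "TemperatureSeries",
    "ThermoDecomposition",
    "mean_binding_energy",
    "reorganization_free_energy",
    "entropy_from_temperature_series",
    "reorganization_energy",
    "decompose",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """Binding free energies at discrete temperatures with 1-sigma errors."""

    temperatures: np.ndarray
    free_energies: np.ndarray
    sigmas: np.ndarray

    def __init__(self, temperatures, free_energies, sigmas) -> None:
        x = np.asarray(temperatures, dtype=float)
        y = np.asarray(free_energies, dtype=float)
        s = np.asarray(sigmas, dtype=float)
        if not (len(x) == len(y) == len(s)) or len(x) < 2:
            raise InvalidInputError("need >= 2 equal-length points")
        if np.any(s <= 0):
            raise InvalidInputError("sigmas must be positive")
        if len(np.unique(x)) != len(x):
            raise InvalidInputError("temperatures must be distinct")
        object.__setattr__(self, "temperatures", x)
        object.__setattr__(self, "free_energies", y)
        object.__setattr__(self, "sigmas", s)


@dataclass(frozen=True)
class ThermoDecomposition:
    """One decomposition row: values in kcal/mol with 2-sigma errors.

    ``entropic_penalty`` is the positive-for-confinement quantity
    -T dS_b evaluated at ``t_ref`` (the sign convention under which
    dG_reorg = dE_reorg + entropic_penalty holds with all printed columns
    positive).  ``dS`` is the signed entropy in kcal/mol/K.
    """

    dG: float
    dG_err2: float
    dE_b: float
    dE_b_err2: float
    dG_reorg: float
    dG_reorg_err2: float
    entropic_penalty: float
    entropic_penalty_err2: float
    dE_reorg: float
    dE_reorg_err2: float
    dS: float
    dS_err2: float
    t_ref: float

    def __post_init__(self) -> None:
        if abs(self.dG_reorg - (self.dG - self.dE_b)) > 1e-9:
            raise InvalidInputError("closure violated: dG_reorg != dG - dE_b")
        if abs(self.dG_reorg - (self.dE_reorg + self.entropic_penalty)) > 1e-9:
            raise InvalidInputError(
                "closure violated: dG_reorg != dE_reorg + entropic_penalty"
            )

    def to_dict(self) -> dict:
        return {
            "t_ref_K": self.t_ref,
            "dG_kcal_mol": self.dG,
            "dG_err2sigma": self.dG_err2,
            "dE_b_kcal_mol": self.dE_b,
            "dE_b_err2sem": self.dE_b_err2,
            "dG_reorg_kcal_mol": self.dG_reorg,
            "dG_reorg_err2sigma": self.dG_reorg_err2,
            "entropic_penalty_kcal_mol": self.entropic_penalty,
            "entropic_penalty_err2sigma": self.entropic_penalty_err2,
            "dE_reorg_kcal_mol": self.dE_reorg,
            "dE_reorg_err2sigma": self.dE_reorg_err2,
            "dS_kcal_mol_K": self.dS,
            "dS_err2sigma": self.dS_err2,
        }


def mean_binding_energy(
    samples: SampleSet,
    t_ref: Optional[float] = None,
    t_eq: float = 0.0,
) -> tuple[float, float]:
    """Mean binding energy dE_b in the fully coupled state and its standard
    error of the mean.

    Uses raw (un-soft-cored) u values: at lambda = 1 bound configurations
    have u <= 0 where the cap is the identity.  The SEM accounts for serial
    correlation through the statistical inefficiency:
    SEM = sd * sqrt(g / n).
    """
    grid = samples.grid
    t_ref = grid.temperatures[0] if t_ref is None else t_ref
    u = samples.for_state(1.0, t_ref, t_min=t_eq)["u_kcal_mol"].to_numpy(float)
    n = len(u)
    if n < 2:
        raise InvalidInputError(
            f"need >= 2 fully-coupled samples after t_eq, got {n}"
        )
    mean = float(np.mean(u))
    sd = float(np.std(u, ddof=1))
    if n < 4 or sd == 0.0:
        g = 1.0
    else:
        g = _diag.statistical_inefficiency(u)
    return mean, sd * math.sqrt(g / n)


def reorganization_free_energy(
    dG: tuple[float, float], dE_b: tuple[float, float]
) -> tuple[float, float]:
    """dG_reorg = dG_b(std) - dE_b with errors summed in quadrature.
    Inputs and output are (value, sigma) at a common sigma level."""
    (g, sg), (e, se) = dG, dE_b
    if not all(map(np.isfinite, (g, sg, e, se))):
        raise InvalidInputError("inputs must be finite")
    return g - e, math.hypot(sg, se)


def entropy_from_temperature_series(
    series: TemperatureSeries,
) -> tuple[float, float, float]:
    """Weighted-least-squares line through dG_b(std)(T).

    Returns (slope m, intercept b, sigma_m) from the closed-form normal
    equations with weights 1/sigma_i^2:

        m = [S_w S_xy - S_x S_y] / [S_w S_xx - S_x^2]
        sigma_m^(-2) = sum_i (x_i - <x>_w)^2 / sigma_i^2

    with <x>_w the weighted mean.  The binding entropy is dS_b = -m and the
    entropic penalty at T is +T m.
    """
    x, y, s = series.temperatures, series.free_energies, series.sigmas
    w = 1.0 / s**2
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    if denom <= 0 or not np.isfinite(denom):
        raise InvalidInputError("singular design: temperatures not distinct")
    m = (sw * sxy - sx * sy) / denom
    b = (sy - m * sx) / sw
    xbar = sx / sw
    sigma_m = 1.0 / math.sqrt(float((w * (x - xbar) ** 2).sum()))
    return float(m), float(b), sigma_m


def reorganization_energy(
    dG_reorg: tuple[float, float], entropic_penalty: tuple[float, float]
) -> tuple[float, float]:
    """dE_reorg = dG_reorg - (-T dS_b) with errors in quadrature."""
    (g, sg), (p, sp) = dG_reorg, entropic_penalty
    if not all(map(np.isfinite, (g, sg, p, sp))):
        raise InvalidInputError("inputs must be finite")
    return g - p, math.hypot(sg, sp)


def decompose(
    samples: SampleSet,
    grid: Optional[StateGrid] = None,
    v_site: Optional[float] = None,
    t_ref: Optional[float] = None,
    t_eq: float = 0.0,
    u_max: float = DEFAULT_UMAX,
) -> ThermoDecomposition:
    """Full decomposition from an equilibrated SampleSet spanning the grid.

    One multistate solve over all (lambda, T) states on data after ``t_eq``,
    binding free energies at every temperature, the WLS entropy slope, the
    mean binding energy, and the closure-consistent assembly.  Needs at
    least two temperatures in the grid.
    """
    grid = grid or samples.grid
    if grid.n_temperature < 2:
        raise InvalidInputError("entropy decomposition needs >= 2 temperatures")
    t_ref = grid.temperatures[0] if t_ref is None else t_ref
    v_site = _diag._default_vsite(samples, v_site)
    sub = samples.time_window(t_min=t_eq)
    res = _uwham.solve_uwham(sub, grid, u_max=u_max)
    temps, dgs, sigs = [], [], []
    for t in grid.temperatures:
        dg, sig = _uwham.binding_free_energy(res, grid, t, v_site)
        temps.append(t)
        dgs.append(dg)
        sigs.append(max(sig, 1e-12))
    series = TemperatureSeries(temps, dgs, sigs)
    m, _, sigma_m = entropy_from_temperature_series(series)

    i_ref = list(grid.temperatures).index(t_ref)
    dG, dG_sig = dgs[i_ref], sigs[i_ref]
    dE_b, sem = mean_binding_energy(sub, t_ref=t_ref)
    dG_reorg, dG_reorg_sig = reorganization_free_energy((dG, dG_sig), (dE_b, sem))
    penalty, penalty_sig = t_ref * m, t_ref * sigma_m
    dE_reorg, dE_reorg_sig = reorganization_energy(
        (dG_reorg, dG_reorg_sig), (penalty, penalty_sig)
    )
    return ThermoDecomposition(
        dG=dG,
        dG_err2=2 * dG_sig,
        dE_b=dE_b,
        dE_b_err2=2 * sem,
        dG_reorg=dG_reorg,
        dG_reorg_err2=2 * dG_reorg_sig,
        entropic_penalty=penalty,
        entropic_penalty_err2=2 * penalty_sig,
        dE_reorg=dE_reorg,
        dE_reorg_err2=2 * dE_reorg_sig,
        dS=-m,
        dS_err2=2 * sigma_m,
        t_ref=t_ref,
    )
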