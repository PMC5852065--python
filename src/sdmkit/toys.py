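"""Analytically solvable receptor-ligand toy systems and synthetic traces.

The estimator and diagnostics machinery in this package is exercised on toy
complexes whose binding free energy is available by one-dimensional
quadrature, and on synthetic time series with controlled equilibration
transients, autocorrelation, and bimodality.  The toy potentials are radial:
the ligand is a point at distance ``d`` from the receptor origin, the
binding energy ``u(d)`` is a radial well, and the decoupled-state energy
``u0`` is a constant (default 0) so that temperature ladders act only on
the coupled term.  Harmonic wells use the ``k * d**2`` convention (no 1/2),
matching the flat-bottom restraint convention.

None of this caricatures peptide chemistry; only the statistical structure
of the sampled binding-energy data is emulated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate

from .alchemical import (
    DEFAULT_UMAX,
    KB,
    BindingSite,
    InvalidInputError,
    StateGrid,
    flat_bottom_restraint,
    softcore_transform,
)
from .sampler import SAMPLE_COLUMNS, SampleSet

__all__ = [
    "ToyComplexModel",
    "harmonic_well",
    "gaussian_well",
    "square_well",
    "bimodal_well",
    "binding_energy",
    "analytic_binding_free_energy",
    "SyntheticTraceSpec",
    "generate_ar1_trace",
    "make_failure_sampleset",
    "independent_sampleset",
]


@dataclass(frozen=True)
class ToyComplexModel:
    """A radial receptor-ligand toy Hamiltonian.

    kinds:
      - ``harmonic_well``: u(d) = depth + spring * d**2
      - ``gaussian_well``: u(d) = depth * exp(-(d/width)**2)
      - ``square_well``:   u(d) = depth for d <= width, else ``shoulder``
        (default 0; a positive shoulder emulates the clashy unbound
        configurations that pile up at the soft-core cap)
      - ``bimodal_well``:  two parabolic basins at d=0 (depth) and
        d=second_center (second_depth) joined at a ridge of absolute energy
        ``barrier`` halfway between the minima; past the second basin the
        outer parabola continues.

    ``u0_value`` is the decoupled-state effective energy (constant).
    """

    kind: str
    depth: float
    width: float = 1.0
    spring: float = 0.0
    second_depth: float = 0.0
    second_center: float = 0.0
    barrier: float = 0.0
    shoulder: float = 0.0
    u0_value: float = 0.0
    site: BindingSite = field(default_factory=lambda: BindingSite(radius=6.0))

    def __post_init__(self) -> None:
        kinds = ("harmonic_well", "gaussian_well", "square_well", "bimodal_well")
        if self.kind not in kinds:
            raise InvalidInputError(f"unknown model kind {self.kind!r}")
        if self.kind in ("gaussian_well", "square_well") and not self.width > 0:
            raise InvalidInputError("width must be positive")
        if self.kind == "bimodal_well":
            if not self.second_center > 0:
                raise InvalidInputError("bimodal_well needs second_center > 0")
            if self.barrier <= max(self.depth, self.second_depth):
                raise InvalidInputError(
                    "bimodal_well barrier must lie above both minima"
                )

    def energy_radial(self, d) -> np.ndarray:
        """Binding energy u at radial distance(s) d, kcal/mol."""
        d = np.asarray(d, dtype=float)
        if self.kind == "harmonic_well":
            return self.depth + self.spring * d**2
        if self.kind == "gaussian_well":
            return self.depth * np.exp(-((d / self.width) ** 2))
        if self.kind == "square_well":
            return np.where(d <= self.width, self.depth, self.shoulder)
        # bimodal: two parabolas pinned to pass through the ridge point
        mid = 0.5 * self.second_center
        k1 = (self.barrier - self.depth) / mid**2
        k2 = (self.barrier - self.second_depth) / (self.second_center - mid) ** 2
        p1 = self.depth + k1 * d**2
        p2 = self.second_depth + k2 * (d - self.second_center) ** 2
        return np.minimum(p1, p2)

    def describe(self) -> dict:
        d = {
            "kind": self.kind,
            "depth": self.depth,
            "width": self.width,
            "spring": self.spring,
            "second_depth": self.second_depth,
            "second_center": self.second_center,
            "barrier": self.barrier,
            "shoulder": self.shoulder,
            "u0_value": self.u0_value,
            "site_radius": self.site.radius,
            "site_force_constant": self.site.force_constant,
        }
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.describe(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def radial_breakpoints(self) -> list[float]:
        """Radii where u(d) or the restraint is non-smooth (quadrature and
        sampling grids must not straddle these)."""
        pts = [self.site.radius]
        if self.kind == "square_well":
            pts.append(self.width)
        if self.kind == "bimodal_well":
            pts.extend([0.5 * self.second_center, self.second_center])
        return sorted(set(pts))


def harmonic_well(
    depth: float, spring: float, site: Optional[BindingSite] = None, **kw
) -> ToyComplexModel:
    site = site or BindingSite(radius=6.0)
    return ToyComplexModel("harmonic_well", depth=depth, spring=spring, site=site, **kw)


def gaussian_well(
    depth: float, width: float, site: Optional[BindingSite] = None, **kw
) -> ToyComplexModel:
    site = site or BindingSite(radius=6.0)
    return ToyComplexModel("gaussian_well", depth=depth, width=width, site=site, **kw)


def square_well(
    depth: float, width: float, site: Optional[BindingSite] = None, **kw
) -> ToyComplexModel:
    site = site or BindingSite(radius=6.0)
    return ToyComplexModel("square_well", depth=depth, width=width, site=site, **kw)


def bimodal_well(
    depth: float,
    second_depth: float,
    second_center: float,
    barrier: float,
    site: Optional[BindingSite] = None,
    **kw,
) -> ToyComplexModel:
    site = site or BindingSite(radius=6.0)
    return ToyComplexModel(
        "bimodal_well",
        depth=depth,
        second_depth=second_depth,
        second_center=second_center,
        barrier=barrier,
        site=site,
        **kw,
    )


def binding_energy(model: ToyComplexModel, position) -> "EnergyPair":
    """Binding energy of a ligand point at ``position`` (3-vector, Angstrom)."""
    from .alchemical import EnergyPair

    pos = np.asarray(position, dtype=float).reshape(3)
    d = float(np.linalg.norm(pos))
    return EnergyPair(u0=model.u0_value, u=float(model.energy_radial(d)))


def analytic_binding_free_energy(
    model: ToyComplexModel,
    temperature: float,
    u_max: float = DEFAULT_UMAX,
    include_restraint: bool = True,
    apply_softcore: bool = True,
    kb: float = KB,
) -> float:
    """Excess binding free energy of a radial toy model by 1-D quadrature.

    With ``include_restraint=True`` (default) this is exactly the free-energy
    difference the alchemical ladder measures:

        dG_b = -kT ln [ int e^{-beta (u'(r) + W(r))} r^2 dr
                        / int e^{-beta W(r)} r^2 dr ]

    with W the flat-bottom site restraint and u' the (optionally soft-cored)
    binding energy, integrated out to where the restraint weight underflows.
    With ``include_restraint=False`` the integrals run over the site sphere
    only and the denominator is the site volume, i.e. the textbook
    site-average of e^{-beta u}.  This is the brute-force oracle for all
    estimator tests; adaptive quadrature to <= 1e-8 relative error.
    """
    beta = 1.0 / (kb * temperature)

    def u_eff(r):
        u = model.energy_radial(r)
        return softcore_transform(u, u_max) if apply_softcore else u

    if include_restraint:
        # integrate until the restraint factor is < 1e-18
        k = max(model.site.force_constant, 1e-12)
        tail = math.sqrt(41.5 / (beta * k))
        r_hi = model.site.radius + tail

        def num(r):
            return np.exp(-beta * (u_eff(r) + flat_bottom_restraint(r, model.site))) * r**2

        def den(r):
            return np.exp(-beta * flat_bottom_restraint(r, model.site)) * r**2
    else:
        r_hi = model.site.radius

        def num(r):
            return np.exp(-beta * u_eff(r)) * r**2

        def den(r):
            return r**2

    # split at potential kinks/discontinuities for quadrature robustness
    pts = {model.site.radius}
    if model.kind == "square_well":
        pts.add(model.width)
    if model.kind == "bimodal_well":
        pts.add(0.5 * model.second_center)
        pts.add(model.second_center)
    points = sorted(p for p in pts if 0 < p < r_hi)
    zn, en = integrate.quad(num, 0.0, r_hi, points=points, epsabs=0.0,
                            epsrel=1e-10, limit=400)
    zd, ed = integrate.quad(den, 0.0, r_hi, points=points, epsabs=0.0,
                            epsrel=1e-10, limit=400)
    if zn <= 0 or zd <= 0 or en / zn > 1e-8 or ed / zd > 1e-8:
        raise ArithmeticError(
            f"quadrature did not converge (Z={zn}+-{en}, Z0={zd}+-{ed})"
        )
    return -kb * temperature * math.log(zn / zd)


# ---------------------------------------------------------------------------
# Synthetic time series


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Specification of an AR(1) series with an initial transient.

    The stationary part has standard deviation ``sigma`` and lag-t
    autocorrelation ``phi**t``; an additive exponential transient of initial
    amplitude ``transient_amplitude`` decays with time constant
    ``transient_length / 4`` (i.e., < 2% of the amplitude survives past the
    stated length).
    """

    n: int
    phi: float = 0.0
    sigma: float = 1.0
    mean: float = 0.0
    transient_length: int = 0
    transient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi < 1.0):
            raise InvalidInputError("phi must be in [0, 1)")
        if self.transient_length >= self.n:
            raise InvalidInputError("transient_length must be < n")
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")


def generate_ar1_trace(spec: SyntheticTraceSpec) -> np.ndarray:
    """Stationary AR(1) series plus optional exponential-decay transient.

    Reproducible from ``spec.seed`` (counter-based Philox generator).
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    innov_sd = spec.sigma * math.sqrt(1.0 - spec.phi**2)
    x = np.empty(spec.n)
    x[0] = rng.normal(0.0, spec.sigma)
    eps = rng.normal(0.0, innov_sd, size=spec.n - 1) if spec.n > 1 else np.empty(0)
    phi = spec.phi
    if phi == 0.0:
        x[1:] = eps
    else:
        # scipy.signal.lfilter would do; the loop is clearer and n is modest
        for i in range(1, spec.n):
            x[i] = phi * x[i - 1] + eps[i - 1]
    x += spec.mean
    if spec.transient_length > 0 and spec.transient_amplitude != 0.0:
        t = np.arange(spec.n)
        tau = spec.transient_length / 4.0
        x = x + spec.transient_amplitude * np.exp(-t / tau)
    return x


def make_failure_sampleset(
    two_mode_gap: float,
    switch_rate: float,
    n: int = 5000,
    t_ref: float = 300.0,
    deep_mean: float = -120.0,
    mode_sd: float = 4.0,
    seed: int = 0,
) -> SampleSet:
    """Fully-coupled-state series hopping between two binding modes.

    Emulates the failure signature of a ligand with two competing bound
    conformations: the lambda=1 binding-energy distribution is a mixture of
    two Gaussians (means ``deep_mean`` and ``deep_mean + two_mode_gap``) with
    symmetric Markov switching at ``switch_rate`` per sample.  With
    ``switch_rate=0`` the series never leaves its initial (deep) mode, so
    the observed histogram is unimodal despite the two-mode truth.
    """
    if switch_rate < 0:
        raise InvalidInputError("switch_rate must be >= 0")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    mode = np.empty(n, dtype=int)
    mode[0] = 0
    flips = rng.random(n - 1) < switch_rate
    mode[1:] = np.cumsum(flips) % 2
    means = np.array([deep_mean, deep_mean + two_mode_gap])
    u = rng.normal(means[mode], mode_sd)
    grid = StateGrid([0.0, 1.0], [t_ref])
    df = pd.DataFrame(
        {
            "time": np.arange(1.0, n + 1.0),
            "replica": np.zeros(n, dtype=int),
            "lambda": np.ones(n),
            "temperature_K": np.full(n, t_ref),
            "U0_kcal_mol": np.zeros(n),
            "u_kcal_mol": u,
        },
        columns=list(SAMPLE_COLUMNS),
    )
    meta = {
        "seed": int(seed),
        "generator": "make_failure_sampleset",
        "two_mode_gap": float(two_mode_gap),
        "switch_rate": float(switch_rate),
    }
    return SampleSet(df, grid, meta)


def synthetic_reverse_profile(
    kind: str = "transient",
    n_points: int = 500,
    t_total: float = 5000.0,
    transient_length: float = 1000.0,
    bias: float = 4.0,
    noise: float = 0.2,
    plateau: float = -8.0,
    seed: int = 0,
    grow_noise: bool = True,
):
    """Synthetic reverse cumulative profile for equilibration-detection
    studies.

    Emulates the statistical shape of a reverse profile with independent
    per-point noise:

      - ``transient``: an exponential equilibration bias of initial size
        ``bias`` decaying with time constant ``transient_length / 4`` on top
        of the plateau value; the per-point noise grows toward long
        equilibration times as 1/sqrt(fraction of data kept) when
        ``grow_noise`` is set (fewer samples remain).
      - ``step``: the bias is a flat offset for t < transient_length.
      - ``drift``: a linear drift of total size ``bias`` across the whole
        profile with constant noise -- a run that never equilibrated.
      - ``flat``: plateau plus noise only.

    Real profiles are smoother than this (consecutive estimates share most
    of their data); the independent-noise idealization isolates the
    detector's behavior from that smoothing.
    """
    from .diagnostics import FreeEnergyProfile

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    t = np.linspace(0.0, 0.9 * t_total, n_points)
    if grow_noise and kind != "drift":
        s = noise / np.sqrt(1.0 - t / t_total)
    else:
        s = np.full(n_points, noise)
    if kind == "transient":
        y = plateau + bias * np.exp(-t / (transient_length / 4.0))
    elif kind == "step":
        y = plateau + bias * (t < transient_length)
    elif kind == "drift":
        y = plateau + bias * (t / t_total)
    elif kind == "flat":
        y = np.full(n_points, plateau)
    else:
        raise InvalidInputError(f"unknown profile kind {kind!r}")
    y = y + rng.normal(0.0, s)
    return FreeEnergyProfile(t, y, 2.0 * s, "reverse")


def _sample_radii(
    model: ToyComplexModel,
    lam: float,
    beta: float,
    u_max: float,
    n: int,
    rng: np.random.Generator,
    n_grid: int = 40001,
) -> np.ndarray:
    """Exact (grid inverse-CDF) radial sampling from the restrained toy
    Boltzmann distribution of one state.

    The grid is built segment by segment between the model's radial
    breakpoints so that no integration cell straddles a discontinuity
    (a straddling cell would leak samples across the boundary with the
    wrong energy).
    """
    k = max(model.site.force_constant, 1e-12)
    r_hi = model.site.radius + math.sqrt(41.5 / (beta * k))
    edges = [0.0] + [b for b in model.radial_breakpoints() if 0 < b < r_hi] + [r_hi]
    segs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_pts = max(200, int(n_grid * (hi - lo) / r_hi))
        segs.append(np.linspace(lo, hi, n_pts))
    r = np.concatenate(segs)
    logw = (
        -beta
        * (
            lam * softcore_transform(model.energy_radial(r), u_max)
            + flat_bottom_restraint(r, model.site)
        )
        + 2.0 * np.log(np.maximum(r, 1e-300))
    )
    logw -= logw.max()
    w = np.exp(logw)
    dr = np.diff(r)  # zero across segment boundaries (duplicated points)
    cell = 0.5 * (w[1:] + w[:-1]) * dr
    # kill cells that cross a segment boundary (dr already 0 there only if
    # boundaries are duplicated; they are not, so zero them explicitly)
    boundary = np.cumsum([len(s) for s in segs[:-1]]) - 1
    cell[boundary] = 0.0
    cdf = np.concatenate([[0.0], np.cumsum(cell)])
    cdf /= cdf[-1]
    uu = rng.random(n)
    idx = np.searchsorted(cdf, uu, side="right")
    idx = np.clip(idx, 1, len(r) - 1)
    frac = (uu - cdf[idx - 1]) / np.maximum(cdf[idx] - cdf[idx - 1], 1e-300)
    return r[idx - 1] + frac * (r[idx] - r[idx - 1])


def independent_sampleset(
    model: ToyComplexModel,
    grid: StateGrid,
    n_per_state: int,
    u_max: float = DEFAULT_UMAX,
    seed: int = 0,
) -> SampleSet:
    """Independent exact samples from every state of the grid.

    Draws radial configurations from each state's restrained Boltzmann
    distribution by inverse-CDF sampling on a dense grid, bypassing Markov
    chain mixing entirely.  Useful for estimator-focused studies (e.g.,
    ladder-overlap experiments) where sampler convergence must not be a
    confounder.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    lam_all = grid.lam_of_states()
    beta_all = grid.beta_of_states()
    frames = []
    for k in range(grid.n_states):
        radii = _sample_radii(model, lam_all[k], beta_all[k], u_max, n_per_state, rng)
        u = model.energy_radial(radii)
        frames.append(
            pd.DataFrame(
                {
                    "time": np.arange(1.0, n_per_state + 1.0),
                    "replica": np.full(n_per_state, k, dtype=int),
                    "lambda": np.full(n_per_state, lam_all[k]),
                    "temperature_K": np.full(
                        n_per_state, 1.0 / (grid.kb * beta_all[k])
                    ),
                    "U0_kcal_mol": np.full(n_per_state, model.u0_value),
                    "u_kcal_mol": u,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[list(SAMPLE_COLUMNS)]
    meta = {
        "seed": int(seed),
        "generator": "independent_sampleset",
        "model": model.describe(),
        "grid": grid.to_dict(),
    }
    return SampleSet(df, grid, meta)
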