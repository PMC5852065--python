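"""Equilibration and convergence quality control.

Simulations start from configurations atypical of equilibrium, so an
initial stretch of data must be discarded before estimation.  The protocol
implemented here:

1. Build the *reverse cumulative profile*: binding free-energy estimates
   dG_b[t_eq] obtained by discarding all data before a candidate
   equilibration time t_eq.  Early points carry the equilibration bias;
   late points are unbiased but noisy.
2. For each candidate, treat the truncated profile as a series, measure its
   correlation length tau (triangular-windowed autocorrelation sum), the
   statistical inefficiency g = 1 + 2 tau, and the effective number of
   independent points n_eff proportional to (t_max - t_eq) / g.  Pick the
   t_eq that maximizes n_eff: including biased early points inflates g
   through the drift they cause, while discarding too much shrinks the
   numerator.  A curve with no clear interior maximum signals
   non-equilibration.  (Applying the autocorrelation machinery to the
   profile rather than to a raw observable series is a deliberate heuristic;
   it captures the drift-vs-noise trade-off even though the profile is not
   itself a time series of an observable.)
3. Confirm convergence on the *forward cumulative profile* (estimates on
   [t_eq, t] for growing t): uncertainties should shrink monotonically and
   the increment dG/dt should decay to zero.
4. Independently scan for the two structural failure modes: adjacent-state
   ensemble overlap gaps along the lambda ladder (which blow up the Fisher
   variance) and bimodality of the fully-coupled binding-energy
   distribution (competing bound conformations that do not interconvert).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .alchemical import DEFAULT_UMAX, InvalidInputError, StateGrid, softcore_transform
from .sampler import SampleSet
from . import uwham as _uwham

__all__ = [
    "FreeEnergyProfile",
    "EquilibrationReport",
    "OverlapReport",
    "BimodalityReport",
    "autocorrelation_function",
    "correlation_time",
    "statistical_inefficiency",
    "effective_samples",
    "reverse_cumulative_profile",
    "forward_cumulative_profile",
    "fluctuation_profile",
    "select_equilibration_time",
    "ladder_overlap_report",
    "endpoint_bimodality_report",
]

logger = logging.getLogger(__name__)

#: Default cap on the autocorrelation window (lags).
DEFAULT_MAX_LAG = 1000


# ---------------------------------------------------------------------------
# Autocorrelation machinery


def autocorrelation_function(series, max_lag: Optional[int] = None) -> np.ndarray:
    """Normalized autocorrelation C_t for t = 0 .. max_lag.

    Uses the full-series mean and variance with the biased (1/n)
    normalization, so C_0 = 1 exactly.  FFT-based evaluation.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise InvalidInputError(f"series too short for autocorrelation (n={n})")
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    if var <= 0 or not np.isfinite(var):
        raise InvalidInputError("series has zero variance")
    if max_lag is None:
        max_lag = n - 1
    max_lag = int(min(max_lag, n - 1))
    nfft = 1
    while nfft < 2 * n:
        nfft <<= 1
    fx = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1] / n
    return acov / (var if var else 1.0)


def correlation_time(
    series,
    t_max_lag: Optional[int] = None,
    truncate_at_first_negative: bool = False,
) -> float:
    """Triangular-windowed correlation length

        tau = sum_{t=1}^{t_max - 1} (1 - t / t_max) C_t.

    ``t_max_lag`` defaults to min(n - 1, 1000); the optional truncation at
    the first negative C_t (off by default) suppresses the noise
    accumulation of long windows.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    t_max = int(min(n - 1, t_max_lag if t_max_lag is not None else DEFAULT_MAX_LAG))
    if t_max < 1:
        return 0.0
    c = autocorrelation_function(x, max_lag=t_max)
    t = np.arange(1, t_max)
    ct = c[1:t_max]
    if truncate_at_first_negative:
        neg = np.nonzero(ct < 0)[0]
        if len(neg):
            ct = ct[: neg[0]]
            t = t[: neg[0]]
    return float(np.sum((1.0 - t / t_max) * ct))


def statistical_inefficiency(series, t_max_lag: Optional[int] = None) -> float:
    """g = 1 + 2 tau, floored at 1 (an anticorrelated series cannot carry
    more information than independent samples for this purpose)."""
    return max(1.0, 1.0 + 2.0 * correlation_time(series, t_max_lag))


def effective_samples(series, n_eq: int, t_max_lag: Optional[int] = None) -> float:
    """n_eff = (n - n_eq) / g computed on the series after discarding the
    first ``n_eq`` points (mean and variance recomputed on the remainder)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not (0 <= n_eq < n):
        raise InvalidInputError(f"n_eq must be in [0, n), got {n_eq} with n={n}")
    tail = x[n_eq:]
    if len(tail) < 4:
        g = 1.0
    else:
        try:
            g = statistical_inefficiency(tail, t_max_lag)
        except InvalidInputError:  # constant tail
            g = 1.0
    return (n - n_eq) / g


# ---------------------------------------------------------------------------
# Cumulative free-energy profiles


@dataclass
class FreeEnergyProfile:
    """Sequence of binding free-energy estimates along a time abscissa.

    ``direction='reverse'``: estimates[i] uses data with time >= times[i]
    (times are candidate equilibration times).
    ``direction='forward'``: estimates[i] uses data in [t_eq, times[i]].
    ``sigmas`` are reported at the 2-sigma level (sigma_level records it).
    Failed points (an endpoint state left empty) carry NaN estimates and
    infinite sigmas, and are listed in ``failures``.
    """

    times: np.ndarray
    estimates: np.ndarray
    sigmas: np.ndarray
    direction: str
    sigma_level: float = 2.0
    t_eq: float = 0.0
    failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.times) == len(self.estimates) == len(self.sigmas)):
            raise InvalidInputError("profile arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("profile times must be strictly increasing")
        if self.direction not in ("reverse", "forward"):
            raise InvalidInputError("direction must be 'reverse' or 'forward'")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "dG_kcal_mol": self.estimates,
                f"err{self.sigma_level:g}sigma_kcal_mol": self.sigmas,
            }
        )


def _profile_point(
    samples: SampleSet,
    grid: StateGrid,
    t_lo: float,
    t_hi: float,
    t_ref: float,
    v_site: float,
    u_max: float,
    f_warm: Optional[np.ndarray],
) -> tuple[float, float, Optional[np.ndarray]]:
    sub = samples.time_window(t_lo, t_hi)
    counts = sub.counts() if len(sub) else np.zeros(grid.n_states)
    k0 = grid.index_of(0.0, t_ref)
    k1 = grid.index_of(1.0, t_ref)
    if counts[k0] == 0 or counts[k1] == 0:
        return np.nan, np.inf, f_warm
    try:
        res = _uwham.solve_uwham(sub, grid, u_max=u_max, f_init=f_warm)
    except _uwham.EstimationError:
        return np.nan, np.inf, f_warm
    dg, sig = _uwham.binding_free_energy(res, grid, t_ref, v_site)
    return dg, sig, res.f


def reverse_cumulative_profile(
    samples: SampleSet,
    grid: Optional[StateGrid] = None,
    candidate_times: Optional[Sequence[float]] = None,
    t_ref: Optional[float] = None,
    v_site: Optional[float] = None,
    u_max: float = DEFAULT_UMAX,
    n_candidates: int = 50,
) -> FreeEnergyProfile:
    """dG_b[t_eq] for each candidate equilibration time: one multistate
    solve per candidate, discarding records with time < t_eq uniformly
    across states.  Candidates default to ``n_candidates`` evenly spaced
    discard points over the sampled time range (the last ones keeping at
    least ~10% of the data).  Sigmas are 2 x Fisher sigma.
    """
    grid = grid or samples.grid
    t = samples.data["time"].to_numpy()
    if len(t) == 0:
        raise InvalidInputError("empty sample set")
    t_lo, t_hi = float(t.min()), float(t.max())
    t_ref = grid.temperatures[0] if t_ref is None else t_ref
    v_site = _default_vsite(samples, v_site)
    if candidate_times is None:
        candidate_times = np.linspace(t_lo, t_lo + 0.9 * (t_hi - t_lo), n_candidates)
    cands = np.asarray(candidate_times, dtype=float)
    if np.any(cands < t_lo) or np.any(cands > t_hi):
        raise InvalidInputError("candidate times outside the sampled range")
    est, sig = np.empty(len(cands)), np.empty(len(cands))
    f_warm: Optional[np.ndarray] = None
    failures = []
    for i, tc in enumerate(cands):
        dg, s, f_warm = _profile_point(
            samples, grid, tc, np.inf, t_ref, v_site, u_max, f_warm
        )
        est[i], sig[i] = dg, 2.0 * s
        if not np.isfinite(dg):
            failures.append(float(tc))
    return FreeEnergyProfile(cands, est, sig, "reverse", failures=failures)


def forward_cumulative_profile(
    samples: SampleSet,
    grid: Optional[StateGrid] = None,
    t_eq: float = 0.0,
    checkpoints: Optional[Sequence[float]] = None,
    t_ref: Optional[float] = None,
    v_site: Optional[float] = None,
    u_max: float = DEFAULT_UMAX,
    n_checkpoints: int = 20,
) -> FreeEnergyProfile:
    """dG_b on [t_eq, t] for each checkpoint t > t_eq."""
    grid = grid or samples.grid
    t = samples.data["time"].to_numpy()
    if len(t) == 0:
        raise InvalidInputError("empty sample set")
    t_hi = float(t.max())
    if t_eq >= t_hi:
        raise InvalidInputError("t_eq must precede the last checkpoint")
    t_ref = grid.temperatures[0] if t_ref is None else t_ref
    v_site = _default_vsite(samples, v_site)
    if checkpoints is None:
        checkpoints = np.linspace(
            t_eq + 0.1 * (t_hi - t_eq), t_hi, n_checkpoints
        )
    cps = np.asarray(checkpoints, dtype=float)
    if np.any(cps <= t_eq):
        raise InvalidInputError("checkpoints must lie after t_eq")
    est, sig = np.empty(len(cps)), np.empty(len(cps))
    f_warm: Optional[np.ndarray] = None
    failures = []
    for i, tc in enumerate(cps):
        dg, s, f_warm = _profile_point(
            samples, grid, t_eq, tc, t_ref, v_site, u_max, f_warm
        )
        est[i], sig[i] = dg, 2.0 * s
        if not np.isfinite(dg):
            failures.append(float(tc))
    return FreeEnergyProfile(cps, est, sig, "forward", t_eq=t_eq, failures=failures)


def fluctuation_profile(forward: FreeEnergyProfile) -> pd.DataFrame:
    """Finite-difference increments dG/dt of a forward profile: the
    differential effect of adding the samples between consecutive
    checkpoints.  Decays to zero for converged runs."""
    if len(forward) < 2:
        raise InvalidInputError("need at least 2 checkpoints")
    dt = np.diff(forward.times)
    dg = np.diff(forward.estimates)
    return pd.DataFrame(
        {"time": forward.times[1:], "dG_per_time": dg / dt}
    )


def _default_vsite(samples: SampleSet, v_site: Optional[float]) -> float:
    if v_site is not None:
        return v_site
    site_r = samples.meta.get("model", {}).get("site_radius") if samples.meta else None
    if site_r:
        from .alchemical import sphere_site_volume

        return sphere_site_volume(float(site_r))
    from .alchemical import STANDARD_VOLUME

    return STANDARD_VOLUME  # makes the correction zero when nothing is known


# ---------------------------------------------------------------------------
# Equilibration-time selection


@dataclass
class EquilibrationReport:
    """Outcome of the n_eff-maximizing equilibration scan.

    ``t_eq`` is set only for an interior maximum; ``rationale`` is one of
    ``interior_maximum``, ``boundary_maximum`` (n_eff still rising at the
    last candidate), or ``no_maximum`` (argmax in the final stretch, or no
    prominent peak -- the non-equilibration verdict).
    """

    t_eq: Optional[float]
    rationale: str
    candidate_times: np.ndarray
    n_eff_curve: np.ndarray
    tau_curve: np.ndarray
    argmax_index: int

    def to_dict(self) -> dict:
        return {
            "t_eq": None if self.t_eq is None else float(self.t_eq),
            "rationale": self.rationale,
            "argmax_index": int(self.argmax_index),
            "candidate_times": self.candidate_times.tolist(),
            "n_eff_curve": self.n_eff_curve.tolist(),
            "tau_curve": self.tau_curve.tolist(),
        }


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    window = max(3, int(window)) | 1  # odd
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(yp, kernel, mode="valid")


def select_equilibration_time(
    profile: FreeEnergyProfile,
    min_tail: int = 8,
    final_fraction: float = 0.1,
    check_prominence: bool = True,
    rel_prominence: float = 0.1,
    t_max_lag: Optional[int] = None,
) -> EquilibrationReport:
    """Pick the equilibration time that maximizes the effective number of
    independent points of the truncated reverse cumulative profile.

    For every candidate i the tail ``estimates[i:]`` yields a correlation
    length tau_i, an inefficiency g_i = 1 + 2 tau_i, and
    n_eff_i = (M - i) / g_i (M = number of profile points).  The argmax
    (ties broken toward the smallest t_eq) is accepted as an interior
    maximum unless it falls in the final ``final_fraction`` of candidates,
    or -- when ``check_prominence`` is on -- the moving-average-smoothed
    n_eff curve has no peak exceeding both of its end values by
    ``rel_prominence`` (relatively).  The prominence test is this package's
    quantification of "no clear maximum": a profile with pure drift yields
    a flat, structureless n_eff curve whose argmax is noise.  An argmax at
    the first candidates (index < 2) is always accepted: the profile is
    flat from the start, i.e. already equilibrated.
    """
    if len(profile) < min_tail:
        raise InvalidInputError(f"profile needs >= {min_tail} points")
    y = profile.estimates
    if np.any(~np.isfinite(y)):
        raise InvalidInputError(
            "profile contains failed points; fix the ladder or window first"
        )
    m = len(y)
    n_cand = m - min_tail + 1
    taus = np.empty(n_cand)
    neff = np.empty(n_cand)
    for i in range(n_cand):
        tail = y[i:]
        try:
            taus[i] = max(0.0, correlation_time(tail, t_max_lag))
        except InvalidInputError:
            taus[i] = 0.0
        neff[i] = (m - i) / (1.0 + 2.0 * taus[i])
    cands = profile.times[:n_cand]
    arg = int(np.argmax(neff))  # np.argmax takes the first of ties

    rationale: str
    t_eq: Optional[float]
    if arg == n_cand - 1 and n_cand > 2:
        rationale, t_eq = "boundary_maximum", None
    elif arg >= int(np.ceil((1.0 - final_fraction) * n_cand)) and n_cand > 3:
        rationale, t_eq = "no_maximum", None
    elif arg < 2:
        rationale, t_eq = "interior_maximum", float(cands[arg])
    elif check_prominence:
        smooth = _moving_average(neff, n_cand // 10)
        peak = float(smooth.max())
        ends = max(float(smooth[0]), float(smooth[-1]))
        if peak >= (1.0 + rel_prominence) * ends:
            rationale, t_eq = "interior_maximum", float(cands[arg])
        else:
            rationale, t_eq = "no_maximum", None
    else:
        rationale, t_eq = "interior_maximum", float(cands[arg])
    if rationale != "interior_maximum":
        logger.info("no clear n_eff maximum (%s): not equilibrated", rationale)
    return EquilibrationReport(
        t_eq=t_eq,
        rationale=rationale,
        candidate_times=np.asarray(cands, dtype=float),
        n_eff_curve=neff,
        tau_curve=taus,
        argmax_index=arg,
    )


# ---------------------------------------------------------------------------
# Structural failure detection


@dataclass
class OverlapReport:
    """Adjacent-lambda ensemble overlap along the ladder.

    ``pairs`` has one row per adjacent lambda pair per temperature with the
    histogram-intersection overlap score in [0, 1] and a gap flag;
    ``capped_states`` lists states whose soft-cored binding energies pile up
    at the u_max cap (> 95% within 1% of u_max), the signature of a
    decoupled state that never samples bound configurations.
    """

    pairs: pd.DataFrame
    capped_states: list
    threshold: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.pairs[self.pairs["gap_flag"]]

    @property
    def any_gap(self) -> bool:
        return bool(self.pairs["gap_flag"].any()) or len(self.capped_states) > 0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_flagged_pairs": int(self.pairs["gap_flag"].sum()),
            "capped_states": self.capped_states,
            "pairs": self.pairs.to_dict(orient="records"),
        }


def _histogram_intersection(a: np.ndarray, b: np.ndarray, bins: int = 50) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def ladder_overlap_report(
    samples: SampleSet,
    grid: Optional[StateGrid] = None,
    u_max: float = DEFAULT_UMAX,
    threshold: float = 0.03,
    bins: int = 50,
    cap_fraction: float = 0.95,
    cap_rtol: float = 0.01,
) -> OverlapReport:
    """Score ensemble overlap of every adjacent lambda pair at each
    temperature.

    For the pair (a, b) the reduced-energy difference
    d = u_hat_b(x) - u_hat_a(x) = beta (lambda_b - lambda_a) u'(x) is
    histogrammed (``bins`` bins over the pooled range) once with samples
    from state a and once with samples from b; the overlap score is the
    intersection mass of the two normalized histograms.  Scores below
    ``threshold`` are flagged as ladder gaps.  States where more than
    ``cap_fraction`` of the soft-cored binding energies lie within
    ``cap_rtol`` of u_max are flagged as cap-saturated.
    """
    grid = grid or samples.grid
    if grid.n_lambda < 2:
        raise InvalidInputError("need at least 2 lambda states")
    idx = samples.state_indices()
    u = samples.data["u_kcal_mol"].to_numpy(dtype=float)
    sc = softcore_transform(u, u_max)
    rows = []
    capped = []
    for it, temp in enumerate(grid.temperatures):
        beta = 1.0 / (grid.kb * temp)
        for il in range(grid.n_lambda - 1):
            ka = grid.flat_index(it, il)
            kb_ = grid.flat_index(it, il + 1)
            ua = sc[idx == ka]
            ub = sc[idx == kb_]
            dlam = grid.lambdas[il + 1] - grid.lambdas[il]
            if len(ua) == 0 or len(ub) == 0:
                score = np.nan
                flag = True
            else:
                score = _histogram_intersection(
                    beta * dlam * ua, beta * dlam * ub, bins
                )
                flag = score < threshold
            rows.append(
                {
                    "temperature_K": temp,
                    "lambda_lo": grid.lambdas[il],
                    "lambda_hi": grid.lambdas[il + 1],
                    "overlap": score,
                    "gap_flag": bool(flag),
                }
            )
    for k in range(grid.n_states):
        uk = sc[idx == k]
        if len(uk) == 0:
            continue
        frac = float(np.mean(uk >= (1.0 - cap_rtol) * u_max))
        if frac > cap_fraction:
            it, il = grid.unravel(k)
            capped.append(
                {
                    "state": int(k),
                    "lambda": grid.lambdas[il],
                    "temperature_K": grid.temperatures[it],
                    "fraction_at_cap": frac,
                }
            )
    return OverlapReport(pd.DataFrame(rows), capped, threshold)


@dataclass
class BimodalityReport:
    """Kernel-density mode scan of the fully-coupled binding-energy
    distribution."""

    n_modes: int
    mode_positions: np.ndarray
    bandwidth: float
    flag: bool
    grid: np.ndarray
    density: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_modes": int(self.n_modes),
            "mode_positions": self.mode_positions.tolist(),
            "bandwidth": float(self.bandwidth),
            "flag": bool(self.flag),
        }


def endpoint_bimodality_report(
    samples: SampleSet,
    t_ref: Optional[float] = None,
    min_samples: int = 500,
    separation_bandwidths: float = 5.0,
    min_mode_height: float = 0.2,
) -> BimodalityReport:
    """Mode count of the lambda = 1 binding-energy distribution.

    A Gaussian kernel density with the Silverman bandwidth
    ``h = 0.9 min(sd, IQR/1.34) n^(-1/5)`` is evaluated on a dense grid;
    local maxima below ``min_mode_height`` of the global peak are treated
    as ripples (competing bound conformations that matter have comparable
    occupancy, while skewed unimodal data shows only low tail ripples).  The distribution is flagged bimodal when at least two
    modes are separated by more than ``separation_bandwidths`` times the
    bandwidth: the signature of competing bound conformations whose
    relative populations the run cannot pin down.
    """
    grid = samples.grid
    t_ref = grid.temperatures[0] if t_ref is None else t_ref
    u = samples.for_state(1.0, t_ref)["u_kcal_mol"].to_numpy(dtype=float)
    n = len(u)
    if n < min_samples:
        raise InvalidInputError(
            f"need >= {min_samples} fully-coupled samples, got {n}"
        )
    sd = float(np.std(u, ddof=1))
    iqr = float(np.subtract(*np.percentile(u, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return BimodalityReport(1, np.array([u[0]]), 0.0, False,
                                np.array([u[0]]), np.array([np.inf]))
    h = 0.9 * scale * n ** (-0.2)
    kde = gaussian_kde(u, bw_method=h / sd)
    lo, hi = u.min() - 3 * h, u.max() + 3 * h
    xs = np.linspace(lo, hi, 1024)
    dens = kde(xs)
    peak = dens.max()
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    mode_idx = np.nonzero(interior & (dens[1:-1] >= min_mode_height * peak))[0] + 1
    modes = xs[mode_idx]
    flag = False
    if len(modes) >= 2:
        flag = bool(np.max(modes) - np.min(modes) > separation_bandwidths * h)
    return BimodalityReport(len(modes), modes, h, flag, xs, dens)


# ---------------------------------------------------------------------------
# Assembled diagnostics


def run_diagnostics(
    samples: SampleSet,
    grid: Optional[StateGrid] = None,
    t_ref: Optional[float] = None,
    v_site: Optional[float] = None,
    u_max: float = DEFAULT_UMAX,
    n_candidates: int = 50,
) -> dict:
    """Full quality-control pass: reverse profile, equilibration selection,
    forward profile from the chosen t_eq, ladder overlap, and endpoint
    bimodality.  Returns a JSON-serializable report; ``converged`` is False
    whenever equilibration fails or a structural flag fires."""
    grid = grid or samples.grid
    rev = reverse_cumulative_profile(
        samples, grid, t_ref=t_ref, v_site=v_site, u_max=u_max,
        n_candidates=n_candidates,
    )
    report: dict = {"reverse_profile": rev.to_frame().to_dict(orient="list")}
    if rev.failures or np.any(~np.isfinite(rev.estimates)):
        eq = None
        report["equilibration"] = {
            "t_eq": None,
            "rationale": "profile_failures",
        }
    else:
        eq = select_equilibration_time(rev)
        report["equilibration"] = eq.to_dict()
    t_eq = report["equilibration"]["t_eq"]
    if t_eq is not None:
        fwd = forward_cumulative_profile(
            samples, grid, t_eq=t_eq, t_ref=t_ref, v_site=v_site, u_max=u_max
        )
        report["forward_profile"] = fwd.to_frame().to_dict(orient="list")
        report["fluctuations"] = fluctuation_profile(fwd).to_dict(orient="list")
    overlap = ladder_overlap_report(samples, grid, u_max=u_max)
    report["ladder_overlap"] = overlap.to_dict()
    try:
        bim = endpoint_bimodality_report(samples, t_ref=t_ref)
        report["endpoint_bimodality"] = bim.to_dict()
        bimodal = bim.flag
    except InvalidInputError:
        report["endpoint_bimodality"] = None
        bimodal = False
    report["converged"] = bool(
        t_eq is not None and not overlap.any_gap and not bimodal
    )
    return report
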