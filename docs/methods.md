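# Methods

This note records the models, conventions, and numerical choices behind
`sdmkit`, in the order the pipeline runs.

## Alchemical model and units

All energies are kcal/mol with `kB = 0.0019872 kcal/mol/K`; every routine
accepts `kb=1` for dimensionless toy work.  A thermodynamic state is a pair
(λ, T); the reduced potential of a configuration with decoupled energy `u0`
and binding energy `u` is `β (u0 + λ u′)`, exactly linear in λ at fixed
configuration.  The soft-core cap `u′ = u_max tanh(u/u_max)` (positive
branch only) is applied identically during sampling and at analysis time:
the capped function *is* the binding energy of the model, so sampler and
estimator always see the same Hamiltonian.  Default `u_max = 1000`
kcal/mol, configurable.

The standard-state term is `−kB T ln(V_site / 1668 Å³)`, with the 1 M
volume-per-molecule constant encoded as the printed literal 1668 rather
than re-derived from Avogadro's number, for arithmetic compatibility with
the literature values it reproduces.  At 300 K this gives +0.365 kcal/mol
for a 6 Å spherical site (905 Å³) and +0.691 kcal/mol for a 5 Å site
(524 Å³); the package always computes the term from its inputs and
hard-codes neither.

**Restraint convention.**  "Force constant k" is ambiguous about the
conventional ½.  The flat-bottom restraint is `k (d − r)²` with
`k = 3.0 kcal/mol/Å²` by default and a `half=True` flag for the other
convention.  The toy harmonic well uses the same no-½ convention
(`u = depth + k d²`) so the two never disagree silently.

## Toy complexes and their oracle

The synthetic-data generator stands in for the molecular system.  Toy
potentials are radial functions of the ligand–origin distance:
harmonic, Gaussian, square (with an optional positive "shoulder" outside
the well emulating clashy unbound configurations), and a two-basin
piecewise-parabolic well whose minima depths, separation, and ridge energy
are stated exactly.  The decoupled energy `u0` is a constant (default 0) so
that the temperature ladder acts only on the coupled term and every
analytic result stays closed-form.

The oracle is 1-D adaptive quadrature of

```
ΔG_b = −kT ln [ ∫ e^{−β(u′(r) + W(r))} r² dr / ∫ e^{−βW(r)} r² dr ]
```

with `W` the flat-bottom restraint, integrated to the radius where the
restraint Boltzmann factor underflows, and with the soft-core applied to
the integrand.  Including the restraint in both integrals makes the oracle
*exactly* the quantity the alchemical ladder measures; the restraint tail
beyond the site radius holds ~20% of the λ = 0 ensemble for the default
site, so a site-only oracle would disagree with an unbiased estimator by
~0.1 kcal/mol.  The textbook site-only average is available via
`include_restraint=False`.  Integration intervals are split at the
potentials' radial breakpoints (well edges, site radius) so no quadrature
or sampling cell straddles a discontinuity — a straddling cell leaks
probability mass across the boundary with the wrong energy, which is large
enough to fake ensemble overlap between otherwise disjoint states.

Two sampling routes exist deliberately: the HREM Markov chain (below), and
`independent_sampleset`, which draws exact independent radial samples per
state by inverse-CDF lookup on a dense per-segment grid.  The exact route
removes sampler convergence as a confounder in estimator-focused studies
(ladder gaps, temperature series); the pipeline acceptance check uses the
Markov chain end to end.

## Replica exchange

One replica per grid state; the state-to-replica map is a permutation at
all times.  Propagation is a Metropolis random walk (uniform cube
proposals) against the reduced potential plus restraint.  Exchanges are
attempted between nearest neighbors in one grid dimension, alternating
λ-even, λ-odd, T-even, T-odd pairings — the exchange pattern is this
package's choice (the sources it follows do not state one); it satisfies
detailed balance because each phase uses disjoint pairs and the Metropolis
ratio.  Time is counted in sweeps; the 25 ps/sample convention of the
molecular runs this emulates is a labeling, not a unit.  Randomness comes
from a counter-based Philox generator keyed by the run seed, making every
SampleSet bit-reproducible.

Default grid: the 26-step λ schedule (dense near 0 where the cap
dominates) crossed with 8 temperatures geometrically spaced over
300–379 K.  Only the temperature endpoints are given by the setup this
emulates; the geometric interior is our choice (equal β-ratio steps give
roughly uniform exchange acceptance when relative energy fluctuations are
scale-free) and is configurable.

## Multistate estimation and errors

The UWHAM/MBAR self-consistent equations are iterated with log-sum-exp
stabilization; once the residual is below 1, damped Newton steps on the
sampled-state block (the exact Hessian of the convex objective) polish to
`tol = 1e-10` on max |Δf|.  The reference state (f = 0) is (λ = 0, lowest
T), the endpoint the binding free energy is defined from.  States with
zero samples are estimated by reweighting.  Cross-temperature reweighting
requires `u0` per sample (β multiplies the whole energy), which is why the
TSV format carries the `U0` column explicitly even though it is zero for
all built-in toys.

The covariance of f is the asymptotic covariance of the pooled-mixture
maximum-likelihood estimate, computed from the normalized weight Gram
matrix `A = WᵀW` in the Woodbury form
`Θ = A + A N^{1/2} M⁺ N^{1/2} A`, `M = I − N^{1/2} A N^{1/2}`.  `M` always
has one structural null direction (weight normalization), which is
projected out; any *additional* near-null eigenvalue means the state
ladder is disconnected — its inverse is kept (floored at 1e−12 of scale),
so the reported variances explode to sentinel scale and a `singular` flag
is raised rather than silently pseudo-inverted away.  This calibrates:
on two-Gaussian problems the Fisher σ matches the empirical scatter of the
estimator over repeated seeds to a few percent.  Reported uncertainties
are 2σ everywhere user-facing (profiles store 2σ with the level recorded);
estimator-level functions return 1σ.

**Correlation check.**  `subsample_error_check` compares the Fisher σ
(which assumes independent samples) with a direct 1/N error: the run is
cut into contiguous time blocks at each fraction, the endpoint Δf is
estimated per block, and the empirical SD across blocks is reported
alongside the mean per-block Fisher σ.  For independent data the ratio
sits near 1; strong serial correlation pushes the empirical error above
the Fisher one.  Blocks are contiguous precisely so that correlation
survives within them; fractions above 1/4 use overlapping windows (at
least 4), which biases the scatter slightly low but keeps it defined.  At
fraction 1 both columns carry the full-data Fisher σ by construction.

## Equilibration and convergence protocol

The reverse cumulative profile re-solves the multistate problem after
discarding all data before each of (by default) 50 evenly spaced candidate
times, warm-starting each solve from the previous solution.  A candidate
that empties an endpoint state yields a NaN/∞ sentinel point, not an
exception.  For each candidate, the *truncated profile* is treated as a
series: its correlation length τ (triangular-windowed autocorrelation sum,
biased 1/n normalization, full-series mean recomputed after each
truncation), inefficiency `g = 1 + 2τ`, and `n_eff ∝ (remaining points)/g`.
The chosen equilibration time maximizes n_eff, ties toward the earliest.
Applying this machinery to a profile rather than a raw observable series
is a documented heuristic: the profile is not a time series, but n_eff
still captures the bias-variance trade-off because early drift inflates g.

"No clear maximum" is operationalized as: argmax in the final 10% of
candidates, **or** no peak of the moving-average-smoothed n_eff curve
exceeding both end values by a 10% relative margin.  The prominence branch
is what actually catches pure-drift profiles, whose n_eff curve is flat
noise (the raw argmax would land anywhere); both thresholds are
configurable and reported.  An argmax at the first two candidates is
accepted as "equilibrated from the start".  An argmax exactly at the last
candidate is labeled `boundary_maximum`.  A usable `t_eq` is returned only
for `interior_maximum`.

The default autocorrelation window is capped at 1000 lags: the triangular
window's truncation bias at that cap is below 1% for correlation times up
to ~10, while an uncapped window on 10⁵-point series would accumulate
enough estimator noise to swamp τ itself.

Convergence is then confirmed on the forward cumulative profile (estimates
on [t_eq, t]) — uncertainties should shrink monotonically and the
finite-difference increment δΔG/δt decay toward zero.

**Failure scans.**  Ladder overlap: for each adjacent λ pair at each
temperature, the reduced-energy difference `β Δλ u′` is histogrammed
(50 bins over the pooled range) separately for the two states' samples;
the overlap score is the intersection mass, flagged below 0.03.  States
with more than 95% of soft-cored energies within 1% of `u_max` are flagged
as cap-saturated.  Both thresholds are this package's quantification of a
qualitative failure description.  Endpoint bimodality: Gaussian KDE with
the Silverman bandwidth `0.9 min(sd, IQR/1.34) n^{−1/5}`; modes below 20%
of the peak height are treated as ripples (skewed unimodal data shows
~8% tail ripples; genuinely competing conformations have comparable
occupancy); the flag fires when two modes are separated by more than five
bandwidths.

## Thermodynamic decomposition

`ΔE_b` is the mean of the *raw* (not soft-cored) binding energies at
(λ = 1, T_ref) after the equilibration cut — at full coupling the cap is
the identity for bound (u ≤ 0) configurations — with
`SEM = sd · sqrt(g/n)`.  `ΔG_b°(T)` at every ladder temperature comes from
one multistate solve; the weighted-least-squares slope m (closed-form
normal equations; slope error `σ_m⁻² = Σ (x−⟨x⟩_w)²/σ_i²`) gives
`ΔS_b° = −m`.  The reported "entropic penalty" is `−T ΔS_b° = +T m`,
the positive-for-confinement convention under which the closure
`ΔG_reorg = ΔE_reorg + penalty` holds with all columns positive; the
signed entropy is reported alongside.  σ_i entering the fit are 1σ,
converted to 2σ only at reporting time.  Both closure identities
(`ΔG_reorg = ΔG − ΔE_b` and the one above) are enforced exactly by
construction and re-validated on every output.

## What the generator does and does not emulate

The toys reproduce the *statistical* structure the analysis assumes:
per-state binding-energy distributions with controllable overlap,
equilibration transients (AR(1) series with an additive exponential decay
whose time constant is a quarter of the stated transient length, so <2% of
the amplitude survives past it), tunable autocorrelation, Markov-switching
bimodality at λ = 1, and profile-level fixtures with independent per-point
noise.  They do not emulate: many-body configurational coupling (the
ligand is a point), rugged landscapes, u0 fluctuations, or the
slow *within-state* mixing of real complexes — the HREM chain on a toy
decorrelates in tens of moves, so passing tests show estimator and
protocol correctness, not that any particular molecular system would be
converged at these run lengths.  Real reverse profiles are also much
smoother than the independent-noise fixtures (consecutive estimates share
most of their data), which makes the n_eff detector conservative on real
runs: it may discard more data than strictly necessary, which costs
precision, not correctness.

## Problem sizes used in the checks

The shipped tests and the acceptance script scale the study down to toy
sizes chosen so every stochastic criterion has comfortable statistical
margin: the pipeline check runs 26 λ × 2 T with 2000 samples/state
(104k samples; the estimate lands within ~1 Fisher σ of the oracle in
repeated seeds); the ladder-gap study uses a sharp square well
(depth −25 kcal/mol, radius 0.3 Å) with 3000 exact samples/state, where
removing λ ∈ (0.1, 0.4) reliably produces a flagged overlap hole and a
10–13× Fisher-σ inflation; equilibration detection uses 20-seed batches of
500-point profiles; the entropy fit uses 100 replicates of an
8-temperature series.  The decomposition check runs 7 λ × 4 T and compares
the fitted entropic penalty against the same WLS fit through exact
quadrature values at the ladder temperatures — the estimand the noisy fit
actually targets, rather than the instantaneous slope at T_ref.

## Known limitations

- The Fisher error of a *severely* under-bridged ladder can be
  overconfident before it becomes singular: with a handful of bridging
  samples the empirical Gram matrix underestimates the true variance even
  as the estimate itself is badly biased.  The overlap scan is the
  primary detector for this regime; the σ explosion is secondary.
- `select_equilibration_time` applied to real (smooth) profiles tends to
  pick later equilibration times than a human would; its thresholds are
  exposed precisely because the "clear maximum" notion is a judgment
  call.
- The histogram-intersection overlap score with a pooled range degrades
  when one state's distribution is extremely wide (all mass in one bin);
  the cap-saturation flag covers the practically relevant such case.
- The bimodality scan sees only what the run sampled: a mode the chain
  never visits (switch rate 0) is invisible by construction, exactly as
  in the motivating failure.
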