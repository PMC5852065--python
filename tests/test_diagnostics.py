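"""Autocorrelation machinery, cumulative profiles, equilibration selection,
and failure detection."""

import numpy as np
import pandas as pd
import pytest

import sdmkit as sk
from sdmkit.alchemical import InvalidInputError
from sdmkit.diagnostics import (
    FreeEnergyProfile,
    fluctuation_profile,
    select_equilibration_time,
)
from sdmkit.sampler import SAMPLE_COLUMNS, SampleSet
from sdmkit.toys import SyntheticTraceSpec, synthetic_reverse_profile


def acf_double_loop(x, max_lag):
    """Naive O(n * t_max) oracle for the normalized autocorrelation with
    full-series mean and biased 1/n normalization."""
    x = np.asarray(x, float)
    n = len(x)
    mu = x.mean()
    var = np.mean((x - mu) ** 2)
    out = np.empty(max_lag + 1)
    for t in range(max_lag + 1):
        s = 0.0
        for i in range(n - t):
            s += (x[i] - mu) * (x[i + t] - mu)
        out[t] = (s / n) / var
    return out


def tau_term_by_term(x, t_max):
    c = acf_double_loop(x, t_max - 1)
    return sum((1.0 - t / t_max) * c[t] for t in range(1, t_max))


class TestAutocorrelation:
    def test_normalized_at_lag_zero(self, rng):
        x = rng.normal(0, 3, 500)
        assert sk.autocorrelation_function(x, max_lag=10)[0] == pytest.approx(1.0)

    def test_iid_lag_one_small(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.0, seed=5))
        c1 = sk.autocorrelation_function(x, max_lag=1)[1]
        assert abs(c1) < 3.0 / np.sqrt(len(x))

    def test_ar1_geometric_decay(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.8, seed=8))
        c = sk.autocorrelation_function(x, max_lag=10)
        for t in range(1, 11):
            assert c[t] == pytest.approx(0.8**t, abs=0.02)

    @pytest.mark.parametrize("seed,n", [(0, 300), (1, 1000), (2, 2000)])
    def test_equals_double_loop_oracle(self, seed, n):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=n, phi=0.6, seed=seed))
        mine = sk.autocorrelation_function(x, max_lag=40)
        oracle = acf_double_loop(x, 40)
        assert np.max(np.abs(mine - oracle)) < 1e-10

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidInputError):
            sk.autocorrelation_function(np.ones(100))
        with pytest.raises(InvalidInputError):
            sk.autocorrelation_function(np.array([1.0, 2.0]))


class TestCorrelationTime:
    def test_white_noise_near_zero(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.0, seed=6))
        assert abs(sk.correlation_time(x)) < 0.1

    def test_ar1_geometric_series(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.9, seed=3))
        assert sk.correlation_time(x) == pytest.approx(9.0, rel=0.10)

    def test_matches_term_by_term_oracle(self):
        """Triangular-windowed sum exactly as printed, on a deterministic
        constant-plus-sinusoid series."""
        t = np.arange(400)
        x = 3.0 + np.sin(2 * np.pi * t / 25.0)
        mine = sk.correlation_time(x, t_max_lag=60)
        oracle = tau_term_by_term(x, 60)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_first_negative_truncation_optional(self):
        t = np.arange(2000)
        x = np.sin(2 * np.pi * t / 50.0)
        full = sk.correlation_time(x, t_max_lag=200)
        trunc = sk.correlation_time(x, t_max_lag=200,
                                    truncate_at_first_negative=True)
        assert trunc != pytest.approx(full)


class TestStatisticalInefficiency:
    def test_white_noise_unity(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.0, seed=9))
        assert sk.statistical_inefficiency(x) == pytest.approx(1.0, abs=0.15)

    def test_ar1_closed_form(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=100_000, phi=0.9, seed=3))
        assert sk.statistical_inefficiency(x) == pytest.approx(19.0, rel=0.10)

    def test_floored_at_one(self):
        # strongly anticorrelated series: tau < 0, g clamps to 1
        x = np.tile([1.0, -1.0], 500) + 0.01 * np.arange(1000) % 1
        assert sk.statistical_inefficiency(x) == 1.0


class TestEffectiveSamples:
    def test_iid_full_series(self):
        x = sk.generate_ar1_trace(SyntheticTraceSpec(n=50_000, phi=0.0, seed=2))
        assert sk.effective_samples(x, 0) == pytest.approx(len(x), rel=0.15)

    def test_short_tail_bound(self, rng):
        x = rng.normal(0, 1, 100)
        assert sk.effective_samples(x, 98) <= 2.0

    def test_out_of_range_rejected(self, rng):
        x = rng.normal(0, 1, 10)
        with pytest.raises(InvalidInputError):
            sk.effective_samples(x, 10)

    def test_maximized_near_transient_end(self):
        """On a raw transient + AR(1) series, n_eff peaks near the true
        transient end."""
        spec = SyntheticTraceSpec(n=4000, phi=0.5, sigma=1.0,
                                  transient_length=800,
                                  transient_amplitude=6.0, seed=14)
        x = sk.generate_ar1_trace(spec)
        cands = np.arange(0, 3000, 100)
        neff = [sk.effective_samples(x, int(c), t_max_lag=500) for c in cands]
        best = cands[int(np.argmax(neff))]
        assert 300 <= best <= 1600


@pytest.fixture(scope="module")
def profile_run(harmonic_model):
    """Stationary exact-sampling run for profile tests."""
    grid = sk.StateGrid([0.0, 0.1, 0.3, 0.6, 1.0], [300.0])
    return sk.independent_sampleset(harmonic_model, grid, 1500, seed=27), grid


class TestProfiles:
    def test_reverse_at_zero_equals_full_estimate(self, profile_run,
                                                  harmonic_model):
        ss, grid = profile_run
        v = harmonic_model.site.volume
        prof = sk.reverse_cumulative_profile(ss, grid, v_site=v,
                                             n_candidates=10)
        res = sk.solve_uwham(ss, grid)
        dg, sig = sk.binding_free_energy(res, grid, 300.0, v)
        assert prof.estimates[0] == pytest.approx(dg, abs=1e-8)
        assert prof.sigmas[0] == pytest.approx(2 * sig, rel=1e-6)

    def test_reverse_and_forward_share_the_full_window(self, profile_run,
                                                       harmonic_model):
        """Reverse at t_eq = t_min and forward at t = t_max use the same
        records, hence the same estimate."""
        ss, grid = profile_run
        v = harmonic_model.site.volume
        rev = sk.reverse_cumulative_profile(ss, grid, v_site=v, n_candidates=8)
        fwd = sk.forward_cumulative_profile(ss, grid, t_eq=float(rev.times[0]),
                                            v_site=v, n_checkpoints=8)
        assert fwd.estimates[-1] == pytest.approx(rev.estimates[0], abs=1e-8)

    def test_stationary_profile_flat_within_bands(self, profile_run,
                                                  harmonic_model):
        ss, grid = profile_run
        v = harmonic_model.site.volume
        prof = sk.reverse_cumulative_profile(ss, grid, v_site=v,
                                             n_candidates=12)
        ref = prof.estimates[0]
        assert np.all(np.abs(prof.estimates - ref) <= prof.sigmas + 1e-12)

    def test_injected_early_bias_detected(self, harmonic_model):
        """Corrupting the first quarter of the fully-coupled data shifts the
        early reverse-profile points beyond their 2-sigma bands while the
        late points agree."""
        grid = sk.StateGrid([0.0, 0.1, 0.3, 0.6, 1.0], [300.0])
        ss = sk.independent_sampleset(harmonic_model, grid, 1500, seed=28)
        v = harmonic_model.site.volume
        df = ss.data.copy()
        early = (df["time"] < 375) & (df["lambda"] == 1.0)
        df.loc[early, "u_kcal_mol"] += 8.0
        biased = SampleSet(df, grid)
        prof = sk.reverse_cumulative_profile(biased, grid, v_site=v,
                                             n_candidates=12)
        late = prof.estimates[-3:].mean()
        assert abs(prof.estimates[0] - late) > prof.sigmas[0]
        assert abs(prof.estimates[-1] - late) <= prof.sigmas[-1]

    def test_forward_uncertainty_shrinks(self, profile_run, harmonic_model):
        ss, grid = profile_run
        v = harmonic_model.site.volume
        fwd = sk.forward_cumulative_profile(ss, grid, t_eq=0.0, v_site=v,
                                            n_checkpoints=10)
        diffs = np.diff(fwd.sigmas)
        assert np.sum(diffs > 0) <= 1  # monotone up to one-point violations

    def test_candidate_leaving_endpoint_empty_flagged(self, harmonic_model):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        # lambda=1 data ends early: late candidates lose the endpoint
        u0 = np.zeros(100)
        df = pd.DataFrame(
            {
                "time": np.concatenate([np.arange(1.0, 101), np.arange(1.0, 51)]),
                "replica": np.repeat([0, 1], [100, 50]),
                "lambda": np.repeat([0.0, 1.0], [100, 50]),
                "temperature_K": 300.0,
                "U0_kcal_mol": 0.0,
                "u_kcal_mol": np.concatenate([u0, np.full(50, -30.0)]),
            }
        )[list(SAMPLE_COLUMNS)]
        ss = SampleSet(df, grid)
        prof = sk.reverse_cumulative_profile(
            ss, grid, candidate_times=[1.0, 80.0], v_site=1668.0
        )
        assert np.isfinite(prof.estimates[0])
        assert np.isnan(prof.estimates[1]) and np.isinf(prof.sigmas[1])
        assert prof.failures == [80.0]


class TestFluctuationProfile:
    def _prof(self, y):
        t = np.arange(1.0, len(y) + 1.0)
        return FreeEnergyProfile(t, np.asarray(y, float),
                                 np.full(len(y), 0.1), "forward")

    def test_constant_profile_zero(self):
        out = fluctuation_profile(self._prof(np.full(10, -8.0)))
        assert np.allclose(out["dG_per_time"], 0.0)

    def test_linear_drift_constant_slope(self):
        out = fluctuation_profile(self._prof(-8.0 + 0.25 * np.arange(10)))
        assert np.allclose(out["dG_per_time"], 0.25)

    def test_converged_run_decays(self, profile_run, harmonic_model):
        ss, grid = profile_run
        fwd = sk.forward_cumulative_profile(
            ss, grid, t_eq=0.0, v_site=harmonic_model.site.volume,
            n_checkpoints=16,
        )
        fl = np.abs(fluctuation_profile(fwd)["dG_per_time"].to_numpy())
        q = len(fl) // 4
        assert fl[-q:].mean() < fl[:q].mean()

    def test_needs_two_checkpoints(self):
        with pytest.raises(InvalidInputError):
            fluctuation_profile(self._prof([1.0]))


class TestSelectEquilibrationTime:
    def test_flat_profile_equilibrated_from_start(self):
        prof = synthetic_reverse_profile(kind="flat", seed=1)
        rep = select_equilibration_time(prof)
        assert rep.rationale == "interior_maximum"
        assert rep.t_eq == prof.times[rep.argmax_index]
        assert rep.argmax_index <= 2

    def test_step_change_recovered(self):
        """Step at candidate index 100 of 500: chosen index in [50, 200] for
        at least 80% of seeds."""
        hits = 0
        for seed in range(20):
            prof = synthetic_reverse_profile(
                kind="step", n_points=500, t_total=5000.0,
                transient_length=0.18 * 5000.0, bias=2.0, seed=seed,
            )
            rep = select_equilibration_time(prof)
            if rep.t_eq is not None and 50 <= rep.argmax_index <= 200:
                hits += 1
        assert hits >= 16

    def test_transient_length_recovered_within_factor_two(self):
        hits = 0
        for seed in range(20):
            prof = synthetic_reverse_profile(kind="transient", bias=4.0,
                                             transient_length=1000.0,
                                             seed=seed)
            rep = select_equilibration_time(prof)
            if rep.t_eq is not None and 500.0 <= rep.t_eq <= 2000.0:
                hits += 1
        assert hits >= 16

    def test_monotone_drift_yields_no_maximum(self):
        misses = 0
        for seed in range(20):
            prof = synthetic_reverse_profile(kind="drift", bias=6.0, seed=seed)
            rep = select_equilibration_time(prof)
            if rep.rationale != "interior_maximum":
                misses += 1
                assert rep.t_eq is None
        assert misses >= 16

    def test_t_eq_only_with_interior_maximum(self):
        """Across fixture kinds and seeds, t_eq is set exactly when the
        rationale is an interior maximum."""
        for kind in ("flat", "step", "drift", "transient"):
            for seed in range(5):
                prof = synthetic_reverse_profile(kind=kind, seed=seed)
                rep = select_equilibration_time(prof)
                assert (rep.t_eq is not None) == (
                    rep.rationale == "interior_maximum"
                )

    def test_short_profile_rejected(self):
        prof = synthetic_reverse_profile(kind="flat", n_points=5, seed=0)
        with pytest.raises(InvalidInputError):
            select_equilibration_time(prof)


def _sampleset_from_state_u(u_by_state, grid, t=300.0):
    frames = []
    for il, u in enumerate(u_by_state):
        frames.append(pd.DataFrame({
            "time": np.arange(1.0, len(u) + 1.0),
            "replica": np.full(len(u), il),
            "lambda": np.full(len(u), grid.lambdas[il]),
            "temperature_K": t,
            "U0_kcal_mol": 0.0,
            "u_kcal_mol": np.asarray(u, float),
        }))
    return SampleSet(pd.concat(frames, ignore_index=True)[list(SAMPLE_COLUMNS)],
                     grid)


class TestLadderOverlap:
    def test_identical_distributions_full_overlap(self):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        ss = _sampleset_from_state_u([np.full(200, -5.0), np.full(200, -5.0)],
                                     grid)
        rep = sk.ladder_overlap_report(ss, grid)
        assert rep.pairs.loc[0, "overlap"] == pytest.approx(1.0)
        assert not rep.any_gap

    def test_disjoint_distributions_flagged(self, rng):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        ss = _sampleset_from_state_u(
            [rng.normal(-100, 1, 300), rng.normal(-5, 1, 300)], grid
        )
        rep = sk.ladder_overlap_report(ss, grid)
        assert rep.pairs.loc[0, "overlap"] == pytest.approx(0.0, abs=1e-12)
        assert rep.pairs.loc[0, "gap_flag"]

    def test_cap_saturation_flagged(self):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        ss = _sampleset_from_state_u(
            [np.full(300, 5000.0), np.full(300, -30.0)], grid
        )
        rep = sk.ladder_overlap_report(ss, grid, u_max=1000.0)
        assert len(rep.capped_states) == 1
        assert rep.capped_states[0]["lambda"] == 0.0
        assert rep.any_gap

    def test_sparse_ladder_gap_detected(self):
        """Removing the lambda states in (0.1, 0.4) on a sharp-transition
        model leaves a flagged overlap hole (the documented pitfall)."""
        m = sk.square_well(-25.0, 0.3)
        fine = [0.0, 0.05] + [round(0.075 + 0.025 * i, 4) for i in range(16)] \
            + [0.55, 0.7, 0.85, 1.0]
        sparse = [x for x in fine if not (0.1 < x < 0.4)]
        dense_ss = sk.independent_sampleset(m, sk.StateGrid(fine, [300.0]),
                                            800, seed=19)
        sparse_ss = sk.independent_sampleset(m, sk.StateGrid(sparse, [300.0]),
                                             800, seed=19)
        assert not sk.ladder_overlap_report(dense_ss).pairs["gap_flag"].any()
        rep = sk.ladder_overlap_report(sparse_ss)
        flagged = rep.flagged
        assert len(flagged) >= 1
        assert (flagged["lambda_lo"] == 0.1).any()

    def test_needs_two_lambdas(self):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        ss = _sampleset_from_state_u([np.zeros(10), np.zeros(10)], grid)
        one = sk.StateGrid([0.0, 1.0], [300.0])
        # grid with a single lambda cannot be built at all; the guard is on
        # the report side for externally supplied grids
        assert sk.ladder_overlap_report(ss, one) is not None


class TestBimodality:
    def test_unimodal_not_flagged(self, rng):
        grid = sk.StateGrid([0.0, 1.0], [300.0])
        ss = _sampleset_from_state_u([np.zeros(10), rng.normal(-60, 4, 2000)],
                                     grid)
        # state 0 has too few points but the endpoint scan only uses lambda=1
        rep = sk.endpoint_bimodality_report(ss)
        assert rep.n_modes == 1 and not rep.flag

    def test_constructed_bimodality_flagged(self):
        ss = sk.make_failure_sampleset(60.0, 0.5, n=5000, seed=2)
        rep = sk.endpoint_bimodality_report(ss)
        assert rep.n_modes == 2 and rep.flag
        spread = np.ptp(rep.mode_positions)
        assert spread > 5 * rep.bandwidth

    def test_hidden_mode_not_flagged_without_interconversion(self):
        """switch_rate = 0: the run is stuck in one mode, so the observed
        histogram is unimodal -- the failure the histogram cannot see."""
        ss = sk.make_failure_sampleset(60.0, 0.0, n=2000, seed=2)
        rep = sk.endpoint_bimodality_report(ss)
        assert rep.n_modes == 1 and not rep.flag

    def test_minimum_sample_guard(self):
        ss = sk.make_failure_sampleset(60.0, 0.5, n=100, seed=2)
        with pytest.raises(InvalidInputError):
            sk.endpoint_bimodality_report(ss)


class TestRunDiagnostics:
    def test_converged_toy_run(self, profile_run, harmonic_model):
        ss, grid = profile_run
        report = sk.run_diagnostics(ss, grid,
                                    v_site=harmonic_model.site.volume,
                                    n_candidates=12)
        assert report["equilibration"]["t_eq"] is not None
        assert report["converged"]
        assert "forward_profile" in report

    def test_bimodal_fixture_not_converged(self):
        ss = sk.make_failure_sampleset(60.0, 0.5, n=2000, seed=3)
        report = sk.run_diagnostics(ss, n_candidates=12)
        assert not report["converged"]
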