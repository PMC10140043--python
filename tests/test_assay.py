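"""Plate-reader endpoint analysis, ratio correction, and fits."""

import math

import numpy as np
import pytest

import aptaswitch as ap
from aptaswitch.assay import (
    DegenerateRatioError,
    correct_nonspecific,
    endpoint,
    fit_beta,
    fit_dose_response,
    regulation_ratio,
    summarize_replicates,
    welch_ttest,
)
from aptaswitch.synthetic import TraceGeneratorParams, generate_trace


def flat_trace(level, n=60, well="w"):
    return ap.KineticTrace(
        well=well, times=tuple(10.0 * k for k in range(n)), fluorescence=(level,) * n
    )


def result(corrected, well="w"):
    return ap.AssayResult(
        well=well,
        endpoint=corrected,
        background=0.0,
        drift_correction=0.0,
        corrected_endpoint=corrected,
    )


class TestEndpoint:
    def test_constant_traces_cancel(self):
        r = endpoint(flat_trace(500.0), flat_trace(80.0))
        assert r.corrected_endpoint == 0.0

    def test_trace_equal_to_no_dna_cancels(self):
        p = TraceGeneratorParams(plateau=900.0, drift_slope=0.4, seed=1)
        t = generate_trace(p)
        assert endpoint(t, t).corrected_endpoint == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_logistic_recovers_plateau_exactly(self):
        t = generate_trace(TraceGeneratorParams(plateau=12_345.0, seed=0))
        nodna = generate_trace(TraceGeneratorParams(plateau=0.0, seed=0))
        assert endpoint(t, nodna).corrected_endpoint == 12_345.0

    def test_noisy_logistic_recovers_plateau_within_tolerance(self):
        sigma = 40.0
        t = generate_trace(TraceGeneratorParams(plateau=8000.0, noise_sd=sigma, seed=7))
        nodna = generate_trace(TraceGeneratorParams(plateau=0.0, seed=7))
        r = endpoint(t, nodna)
        assert r.corrected_endpoint == pytest.approx(
            8000.0, abs=3 * sigma / math.sqrt(15) * 2
        )

    def test_offset_invariance(self):
        """Adding a constant to both trace and no-DNA leaves the corrected
        endpoint unchanged."""
        p = TraceGeneratorParams(plateau=5000.0, drift_slope=0.2, seed=3)
        t = generate_trace(p)
        nodna = generate_trace(TraceGeneratorParams(plateau=0.0, drift_slope=0.2, seed=4))

        def shift(tr, c):
            return ap.KineticTrace(
                well=tr.well,
                times=tr.times,
                fluorescence=tuple(f + c for f in tr.fluorescence),
            )

        base = endpoint(t, nodna).corrected_endpoint
        shifted = endpoint(shift(t, 777.0), shift(nodna, 777.0)).corrected_endpoint
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_too_few_points_names_the_trace(self):
        short = ap.KineticTrace(
            well="bad", times=(0.0, 10.0), fluorescence=(1.0, 2.0)
        )
        with pytest.raises(ValueError, match="bad"):
            endpoint(short, flat_trace(0.0))

    def test_nan_rejected_at_ingestion(self):
        with pytest.raises(ValueError):
            ap.KineticTrace(well="w", times=(0.0, 1.0), fluorescence=(1.0, float("nan")))


class TestRegulationRatio:
    def test_equal_endpoints_unity(self):
        assert regulation_ratio(result(100.0), result(100.0), ap.Mode.ON) == 1.0

    def test_off_mode_halving_gives_two(self):
        assert regulation_ratio(result(50.0), result(100.0), ap.Mode.OFF) == 2.0

    def test_nonpositive_endpoint_raises(self):
        with pytest.raises(DegenerateRatioError):
            regulation_ratio(result(-5.0), result(100.0), ap.Mode.ON)

    def test_ratio_matches_generator_plateaus(self):
        p_on = TraceGeneratorParams(plateau=9000.0, seed=1)
        p_off = TraceGeneratorParams(plateau=3000.0, seed=2)
        nodna = generate_trace(TraceGeneratorParams(plateau=0.0, seed=3))
        on = endpoint(generate_trace(p_on), nodna)
        off = endpoint(generate_trace(p_off), nodna)
        assert regulation_ratio(on, off, ap.Mode.ON) == pytest.approx(3.0, rel=1e-9)


class TestNonspecificCorrection:
    def test_published_worked_examples(self):
        """The three printed correction cases: a control moving opposite
        to an OFF switch multiplies, one moving with it divides."""
        assert correct_nonspecific(1.74, 1 / 2.37, ap.Mode.OFF) == pytest.approx(
            4.1, abs=0.05
        )
        assert correct_nonspecific(237.0, 11.0, ap.Mode.OFF) == pytest.approx(
            21.5, abs=0.05
        )
        assert correct_nonspecific(3.2, 1 / 1.65, ap.Mode.OFF) == pytest.approx(
            5.3, abs=0.05
        )

    def test_unit_control_is_identity(self):
        assert correct_nonspecific(7.7, 1.0, ap.Mode.ON) == 7.7

    def test_multiplicative_in_two_steps(self):
        one = correct_nonspecific(10.0, 2.0 * 1.25, ap.Mode.ON)
        two = correct_nonspecific(
            correct_nonspecific(10.0, 2.0, ap.Mode.ON), 1.25, ap.Mode.ON
        )
        assert one == pytest.approx(two, rel=1e-12)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            correct_nonspecific(2.0, 0.0, ap.Mode.OFF)


class TestDoseResponse:
    def hill(self, p, base, amp, k, n):
        p = np.asarray(p, dtype=float)
        return base + amp * np.where(p > 0, p**n / (p**n + k**n), 0.0)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(12)
        concs = np.array([0, 50, 100, 200, 400, 800, 1600, 3200], dtype=float) * 1e-9
        y = self.hill(concs, 1000.0, -900.0, 400e-9, 2.0)
        y = y * (1 + rng.normal(0, 0.05, size=len(y)))
        fit = fit_dose_response(list(concs), list(y))
        assert fit.converged and not fit.degenerate
        assert fit.direction == "repression"
        assert fit.half_max_conc == pytest.approx(400e-9, rel=0.10)

    def test_flat_data_flagged_degenerate(self):
        concs = [0.0, 1e-8, 1e-7, 1e-6]
        fit = fit_dose_response(concs, [100.0] * 4)
        assert fit.degenerate and fit.amplitude == 0.0

    def test_half_max_is_midpoint_of_fitted_curve(self):
        concs = [0.0, 1e-8, 1e-7, 3e-7, 1e-6, 3e-6]
        y = self.hill(concs, 200.0, 800.0, 2.5e-7, 1.3)
        fit = fit_dose_response(concs, list(y))
        mid = fit.predict([fit.half_max_conc])[0]
        assert mid == pytest.approx(fit.baseline + fit.amplitude / 2, rel=1e-6)

    def test_residuals_invariant_to_order(self):
        concs = [0.0, 1e-8, 1e-7, 1e-6, 1e-5]
        y = list(self.hill(concs, 100.0, 500.0, 3e-7, 1.0))
        a = fit_dose_response(concs, y)
        b = fit_dose_response(concs[::-1], y[::-1])
        assert a.rss == pytest.approx(b.rss, abs=1e-9)

    def test_needs_zero_and_four_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_dose_response([1e-9, 2e-9, 4e-9, 8e-9], [1, 2, 3, 4])


class TestBetaFit:
    def test_noiseless_exact_recovery(self):
        dg = np.linspace(-8, 4, 10)
        y = np.exp(3.0 - 0.23 * dg)
        fit = fit_beta(list(dg), list(y))
        assert fit.beta_hat == pytest.approx(0.23, abs=1e-12)
        assert fit.ln_k_hat == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(99)
        dg = rng.uniform(-9, 3, size=34)
        y = np.exp(3.0 - 0.23 * dg + rng.normal(0, 0.3, size=34))
        fit = fit_beta(list(dg), list(y))
        lo, hi = fit.ci95
        assert lo < 0.23 < hi

    def test_ci_coverage_calibrated(self):
        """Across 200 seeded simulated datasets the 95% CI covers the true
        slope between 90% and 99% of the time."""
        rng = np.random.default_rng(2024)
        dg = rng.uniform(-9, 3, size=34)
        hits = 0
        for _ in range(200):
            y = np.exp(3.0 - 0.23 * dg + rng.normal(0, 0.3, size=34))
            lo, hi = fit_beta(list(dg), list(y)).ci95
            hits += lo < 0.23 < hi
        assert 0.90 <= hits / 200 <= 0.99

    def test_identical_dg_values_rejected(self):
        with pytest.raises(ValueError):
            fit_beta([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])

    def test_nonpositive_endpoint_rejected(self):
        with pytest.raises(ValueError):
            fit_beta([1.0, 2.0, 3.0], [2.0, -1.0, 4.0])


class TestReplicatesAndStats:
    def test_summarize_replicates_interval(self):
        vals = [100.0, 110.0, 90.0, 105.0, 95.0, 100.0]
        summary = summarize_replicates([result(v) for v in vals])
        assert summary.mean == pytest.approx(np.mean(vals))
        assert summary.n_replicates == 6
        lo, hi = summary.ci95
        assert lo < summary.mean < hi

    def test_welch_detects_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 8)
        b = rng.normal(13, 1, 8)
        _, p = welch_ttest(list(a), list(b))
        assert p < 0.001
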