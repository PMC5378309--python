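"""Interim engine: model fit, coefficient resampling, predicted power, rules."""

import numpy as np
import pytest
from scipy.special import betaln, gammaln
from scipy.stats import binom

from cbatt import (
    CoefficientDraws,
    InsufficientDataError,
    LogisticCurve,
    StageData,
    decide_adaptive,
    decide_fixed,
    fit_stage1_model,
    predicted_power,
    predicted_power_curve,
    sample_coefficients,
)
from cbatt.interim import fixed_design_tail
from cbatt.model import response_rate


def make_draws(pairs):
    pairs = np.asarray(pairs, dtype=float)
    return CoefficientDraws(
        point_estimate=pairs.mean(axis=0),
        covariance=np.cov(pairs.T) if len(pairs) > 1 else np.zeros((2, 2)),
        draws=pairs,
    )


class TestFitStage1Model:
    def test_large_sample_consistency(self, rng):
        true = LogisticCurve(-3.0, 6.0)
        b = rng.uniform(0, 1, 10_000)
        x = (rng.random(10_000) < response_rate(true, b)).astype(int)
        fit = fit_stage1_model(StageData(b, x))
        assert not fit.degenerate
        assert fit.point_estimate[0] == pytest.approx(-3.0, abs=0.15)
        assert fit.point_estimate[1] == pytest.approx(6.0, abs=0.15)

    def test_identical_responses_flagged(self):
        fit = fit_stage1_model(StageData([0.2, 0.5, 0.9], [1, 1, 1]))
        assert fit.degenerate and "all responses 1" in fit.message
        fit = fit_stage1_model(StageData([0.2, 0.5, 0.9], [0, 0, 0]))
        assert fit.degenerate

    def test_perfect_separation_flagged(self):
        fit = fit_stage1_model(StageData([0.5, 0.9], [0, 1]))
        assert fit.degenerate

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            fit_stage1_model(StageData([0.5], [1]))


class TestSampleCoefficients:
    def test_zero_covariance_returns_point_estimate(self, rng):
        fit = CoefficientDraws(np.array([-1.0, 2.0]), np.zeros((2, 2)))
        draws = sample_coefficients(fit, 10, rng)
        assert np.allclose(draws.draws, [-1.0, 2.0])

    def test_mean_matches_point_estimate(self, rng):
        cov = np.array([[0.5, -0.2], [-0.2, 0.8]])
        fit = CoefficientDraws(np.array([-1.0, 2.0]), cov)
        draws = sample_coefficients(fit, 100_000, rng)
        se = np.sqrt(np.diag(cov) / 100_000)
        assert np.all(np.abs(draws.draws.mean(axis=0) - [-1.0, 2.0]) < 4 * se)

    def test_deterministic_given_seed(self):
        fit = CoefficientDraws(np.array([0.0, 1.0]), np.eye(2))
        a = sample_coefficients(fit, 50, np.random.default_rng(3)).draws
        b = sample_coefficients(fit, 50, np.random.default_rng(3)).draws
        assert np.array_equal(a, b)

    def test_non_psd_covariance_repaired(self, rng):
        cov = np.array([[1.0, 0.0], [0.0, -1e-6]])
        fit = CoefficientDraws(np.array([0.0, 0.0]), cov)
        draws = sample_coefficients(fit, 10, rng)
        assert np.all(np.isfinite(draws.draws))
        assert np.allclose(draws.draws[:, 1], 0.0)

    def test_degenerate_fit_rejected(self, rng):
        fit = CoefficientDraws(
            np.array([np.nan, np.nan]), np.full((2, 2), np.nan), degenerate=True
        )
        with pytest.raises(ValueError):
            sample_coefficients(fit, 10, rng)


def betabinom_pmf_reference(k, n, a, b):
    """Independent beta-binomial pmf from log-gamma identities."""
    return np.exp(
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


class TestPredictedPower:
    def test_certain_event(self, rng):
        draws = make_draws([[-1.0, 3.0]] * 5)
        power, _, _ = predicted_power(draws, 0.5, s2=50, required=0)
        assert power == 1.0

    def test_impossible_event(self):
        draws = make_draws([[-1.0, 3.0]] * 5)
        power, _, _ = predicted_power(draws, 0.5, s2=50, required=51)
        assert power == 0.0

    def test_point_mass_reduces_to_binomial_tail(self):
        # all draws give Pi~ = 0.5 exactly: flat curves at log-odds zero
        draws = make_draws([[0.0, 0.0]] * 100)
        power, a, b = predicted_power(draws, 0.3, s2=50, required=25)
        assert power == pytest.approx(float(binom.sf(24, 50, 0.5)), abs=1e-6)
        assert np.isnan(a) and np.isnan(b)

    def test_tail_equals_pmf_enumeration(self):
        rng = np.random.default_rng(11)
        pairs = np.column_stack([rng.normal(-2, 0.8, 500), rng.normal(5, 1.0, 500)])
        power, a, b = predicted_power(make_draws(pairs), 0.4, s2=50, required=22)
        brute = sum(betabinom_pmf_reference(k, 50, a, b) for k in range(22, 51))
        assert power == pytest.approx(brute, abs=1e-12)

    def test_non_increasing_in_required(self):
        rng = np.random.default_rng(5)
        pairs = np.column_stack([rng.normal(-1, 0.5, 400), rng.normal(4, 0.7, 400)])
        draws = make_draws(pairs)
        powers = [
            predicted_power(draws, 0.5, s2=40, required=r)[0] for r in range(0, 42)
        ]
        assert np.all(np.diff(powers) <= 1e-12)


class TestPredictedPowerCurve:
    def test_monotone_for_positive_slope_draws(self):
        rng = np.random.default_rng(9)
        pairs = np.column_stack(
            [rng.normal(-3, 0.5, 300), np.abs(rng.normal(6, 1.0, 300))]
        )
        curve = predicted_power_curve(
            make_draws(pairs), np.arange(0, 0.96, 0.05), s2=50, required=25
        )
        assert np.all(np.diff(curve.powers) >= -1e-12)

    def test_single_point_grid_matches_scalar(self):
        rng = np.random.default_rng(2)
        pairs = np.column_stack([rng.normal(-2, 0.5, 200), rng.normal(5, 1, 200)])
        draws = make_draws(pairs)
        curve = predicted_power_curve(draws, [0.4], s2=50, required=20)
        scalar = predicted_power(draws, 0.4, s2=50, required=20)
        assert curve.powers[0] == pytest.approx(scalar[0], abs=1e-15)

    def test_required_zero_gives_all_ones(self):
        draws = make_draws([[-1.0, 3.0]] * 10)
        curve = predicted_power_curve(draws, [0.1, 0.5, 0.9], s2=30, required=0)
        assert np.all(curve.powers == 1.0)

    def test_decreasing_grid_rejected(self):
        draws = make_draws([[-1.0, 3.0]] * 10)
        with pytest.raises(ValueError):
            predicted_power_curve(draws, [0.5, 0.3], s2=30, required=5)


class TestDecideAdaptive:
    def curve(self, powers, grid=(0.0, 0.05, 0.10, 0.15)):
        from cbatt.interim import PredictedPowerCurve

        k = len(powers)
        return PredictedPowerCurve(
            np.asarray(grid), np.asarray(powers), np.full((k, 2), np.nan)
        )

    def test_minimum_threshold_reaching_target(self):
        d = decide_adaptive(
            self.curve([0.6, 0.75, 0.81, 0.9]), 0.8, 0.8, "AD1"
        )
        assert d.action == "continue" and d.chosen_t2 == 0.10

    def test_ad1_stops_when_no_threshold_qualifies(self):
        d = decide_adaptive(self.curve([0.5, 0.6, 0.7, 0.79]), 0.8, 0.8, "AD1")
        assert d.action == "stop" and d.chosen_t2 is None

    def test_ad2_falls_back_to_max_threshold(self):
        d = decide_adaptive(self.curve([0.4, 0.5, 0.52, 0.55]), 0.8, 0.5, "AD2")
        assert d.action == "continue" and d.chosen_t2 == 0.15

    def test_ad2_stops_below_gamma(self):
        d = decide_adaptive(self.curve([0.2, 0.3, 0.4, 0.45]), 0.8, 0.5, "AD2")
        assert d.action == "stop"

    def test_ad3_never_stops(self):
        d = decide_adaptive(self.curve([0.0, 0.0, 0.0, 0.0]), 0.8, 0.0, "AD3")
        assert d.action == "continue" and d.chosen_t2 == 0.15

    def test_gamma_constraints_enforced(self):
        with pytest.raises(ValueError):
            decide_adaptive(self.curve([0.9] * 4), 0.8, 0.5, "AD1")
        with pytest.raises(ValueError):
            decide_adaptive(self.curve([0.9] * 4), 0.8, 0.5, "AD3")


class TestDecideFixed:
    def test_already_significant_continues(self):
        d = decide_fixed(49, 50, 50, 49, 0.8, "FD1", threshold=0.5)
        assert d.action == "continue"
        assert d.diagnostics["predictive_probability"] == 1.0

    def test_zero_responses_stops(self):
        d = decide_fixed(0, 50, 50, 49, 0.8, "FD1")
        assert d.action == "stop"
        assert d.diagnostics["predictive_probability"] == 0.0

    def test_tail_matches_pmf_enumeration(self):
        tail = fixed_design_tail(26, 50, 50, 49)
        brute = sum(
            betabinom_pmf_reference(k, 50, 26, 24) for k in range(23, 51)
        )
        assert tail == pytest.approx(brute, abs=1e-12)

    def test_fd2_always_continues(self):
        d = decide_fixed(0, 50, 50, 49, 0.8, "FD2", threshold=0.5)
        assert d.action == "continue" and d.chosen_t2 == 0.5

    def test_strict_inequality_at_boundary(self):
        # tail exactly equal to the futility bound must continue (< is strict)
        tail = fixed_design_tail(26, 50, 50, 49)
        d = decide_fixed(26, 50, 50, 49, 1.0 - tail, "FD1")
        assert d.action == "continue"
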