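import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from densitycal import detection as det
from densitycal import synthetic as syn
from densitycal.errors import EstimationError, InvalidArgumentError

BOUNDARIES = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
EDGES = [0.0, 50.0, 100.0, 150.0, 200.0, np.inf]


def const_covariates(n, **extra):
    base = {"jday": np.full(n, 150.0), "min_since_dawn": np.full(n, 200.0)}
    base.update(extra)
    return pd.DataFrame(base)


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------

class TestAicc:
    def test_zero_parameters_equals_minus_two_loglik(self):
        assert det.aicc(-50.0, 0, 100) == 100.0

    def test_large_n_limit_approaches_aic(self):
        aic = -2 * (-100.0) + 2 * 3
        assert det.aicc(-100.0, 3, 10**8) == pytest.approx(aic, abs=1e-3)

    def test_worked_arithmetic(self):
        # -2(-100) + 2*3 + 2*3*4/(50-4) = 206 + 24/46
        assert det.aicc(-100.0, 3, 50) == pytest.approx(206 + 24 / 46)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            det.aicc(-10.0, 3, 4)

    def test_differences_invariant_to_shared_constant(self):
        d0 = det.aicc(-100.0, 2, 50) - det.aicc(-98.0, 3, 50)
        d1 = det.aicc(-100.0 + 7.0, 2, 50) - det.aicc(-98.0 + 7.0, 3, 50)
        assert d0 == pytest.approx(d1)


# ---------------------------------------------------------------------------
# cell probabilities
# ---------------------------------------------------------------------------

class TestRemovalCellProbs:
    def test_instant_availability_concentrates_in_first_interval(self):
        p = det.removal_cell_probs(100.0, BOUNDARIES)
        assert p[0] == pytest.approx(1.0)
        assert p[1:].max() < 1e-10

    def test_vanishing_rate_limit_is_uniform_over_interval_lengths(self):
        p = det.removal_cell_probs(1e-9, [0.0, 1.0, 3.0, 5.0])
        assert p == pytest.approx([0.2, 0.4, 0.4], abs=1e-6)

    def test_sums_to_one(self):
        for phi in (0.05, 0.5, 3.0):
            assert det.removal_cell_probs(phi, BOUNDARIES).sum() == pytest.approx(1.0)

    def test_matches_monte_carlo_frequencies(self):
        phi = 0.5
        intervals = syn.simulate_removal_sample(phi, 100_000, BOUNDARIES, rng=0)
        freq = np.bincount(intervals, minlength=6)[1:] / 100_000
        p = det.removal_cell_probs(phi, BOUNDARIES)
        assert np.max(np.abs(freq - p)) < 0.01

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            det.removal_cell_probs(0.0, BOUNDARIES)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.05, 5.0))
    def test_matches_truncated_exponential_quadrature(self, phi):
        # brute-force oracle: integrate the exponential density per interval
        total = 1 - math.exp(-phi * BOUNDARIES[-1])
        oracle = [quad(lambda t: phi * math.exp(-phi * t), a, b)[0] / total
                  for a, b in zip(BOUNDARIES[:-1], BOUNDARIES[1:])]
        assert det.removal_cell_probs(phi, BOUNDARIES) == pytest.approx(oracle, rel=1e-6)


class TestDistanceCellProbs:
    def test_flat_detection_limit_concentrates_in_unbounded_bin(self):
        p = det.distance_cell_probs(1e6, EDGES)
        assert p[-1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_half_normal_quadrature(self):
        tau = 100.0
        oracle = []
        for a, b in zip(EDGES[:-1], EDGES[1:]):
            hi = b if np.isfinite(b) else 20 * tau
            val = quad(lambda r: 2 * math.pi * r * math.exp(-(r**2) / tau**2), a, hi)[0]
            oracle.append(val / (math.pi * tau**2))
        assert np.max(np.abs(det.distance_cell_probs(tau, EDGES) - oracle)) < 1e-8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(10.0, 500.0))
    def test_sums_to_one(self, tau):
        assert abs(det.distance_cell_probs(tau, EDGES).sum() - 1.0) < 1e-12

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            det.distance_cell_probs(-1.0, EDGES)
        with pytest.raises(InvalidArgumentError):
            det.distance_cell_probs(80.0, [0.0, 50.0, 200.0])  # finite last edge


class TestAvailability:
    def test_boundaries(self):
        assert det.availability(0.0, 5.0) == 0.0
        assert det.availability(0.3, 1e9) == pytest.approx(1.0)

    def test_matches_monte_carlo_exponential_fraction(self, rng):
        draws = rng.exponential(1 / 0.3, size=100_000)
        assert det.availability(0.3, 5.0) == pytest.approx((draws <= 5.0).mean(),
                                                           abs=0.005)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            det.availability(0.3, 0.0)


# ---------------------------------------------------------------------------
# effective detection radius
# ---------------------------------------------------------------------------

class TestEdr:
    def test_half_normal_identity(self):
        assert det.edr(80.0) == 80.0

    def test_balance_integral_returns_tau(self, rng):
        for tau in rng.uniform(20.0, 400.0, size=20):
            assert abs(det.edr_from_balance(tau) - tau) / tau < 1e-6

    def test_doubling_tau_quadruples_effective_area(self):
        a1 = math.pi * det.edr(80.0) ** 2
        a2 = math.pi * det.edr(160.0) ** 2
        assert a2 / a1 == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

class TestRemovalFitting:
    def test_constant_rate_recovery(self):
        intervals = syn.simulate_removal_sample(0.4, 2000, BOUNDARIES, rng=0)
        ranked = det.fit_removal_set(intervals, const_covariates(2000), BOUNDARIES)
        null = [r for r in ranked if r.terms == ()][0]
        assert np.exp(null.params[0]) == pytest.approx(0.4, rel=0.05)

    def test_single_individual_null_fit_is_finite(self):
        model = det.RemovalModel([1], const_covariates(1), BOUNDARIES)
        res = model.fit()
        assert np.all(np.isfinite(res.params))
        assert np.isfinite(res.loglik)

    def test_single_individual_set_raises_estimation_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(EstimationError):
                det.fit_removal_set([1], const_covariates(1), BOUNDARIES)

    def test_time_of_day_effect_selected(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            tod = rng.uniform(0, 420, 4000)
            phi = np.exp(np.log(0.4) + 0.5 * (tod - 210) / 210)
            intervals = syn.simulate_removal_sample(phi, rng=rng)
            cov = const_covariates(4000)
            cov["min_since_dawn"] = tod
            wins += "tod" in det.fit_removal_set(intervals, cov, BOUNDARIES)[0].terms
        assert wins >= 9

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(InvalidArgumentError):
            det.RemovalModel([7], const_covariates(1), BOUNDARIES)


class TestDistanceFitting:
    def test_constant_tau_recovery(self):
        bins = syn.simulate_distance_sample(80.0, 2000, EDGES, rng=0)
        model = det.DistanceModel(bins, const_covariates(2000), EDGES)
        res = model.fit()
        assert np.exp(res.params[0]) == pytest.approx(80.0, rel=0.05)

    def test_all_first_bin_detections_give_small_finite_tau(self):
        model = det.DistanceModel(np.ones(50, dtype=int), const_covariates(50), EDGES)
        res = model.fit()
        tau_hat = float(np.exp(res.params[0]))
        assert np.isfinite(tau_hat) and tau_hat < 60.0

    def test_canopy_effect_selected(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            canopy = rng.normal(0, 1, 4000)
            tau = np.exp(np.log(80.0) + 0.3 * canopy)
            bins = syn.simulate_distance_sample(tau, rng=rng)
            cov = const_covariates(
                4000, canopy_75=canopy,
                urban_hd_md_75=rng.normal(0, 1, 4000),
                urban_total_75=rng.normal(0, 1, 4000),
                d_river=500 * np.exp(0.6 * rng.normal(0, 1, 4000)),
                d_highway=500 * np.exp(0.6 * rng.normal(0, 1, 4000)))
            wins += "canopy" in det.fit_distance_set(bins, cov, EDGES)[0].terms
        assert wins >= 9

    def test_stage1_candidate_enumeration(self):
        cands = det.distance_stage1_candidates()
        assert len(cands) == 16  # null + 3 forms x 2 vars + 3 x 3 combinations
        assert () in cands


class TestJointRecovery:
    def test_median_recovery_over_ten_seeded_fits(self):
        phis, taus = [], []
        for s in range(10):
            rng = np.random.default_rng(s)
            intervals = syn.simulate_removal_sample(0.4, 2000, BOUNDARIES, rng)
            bins = syn.simulate_distance_sample(80.0, 2000, EDGES, rng)
            cov = const_covariates(2000)
            phis.append(np.exp(det.RemovalModel(intervals, cov, BOUNDARIES).fit().params[0]))
            taus.append(np.exp(det.DistanceModel(bins, cov, EDGES).fit().params[0]))
        assert np.median(phis) == pytest.approx(0.4, rel=0.05)
        assert np.median(taus) == pytest.approx(80.0, rel=0.05)


# ---------------------------------------------------------------------------
# offsets
# ---------------------------------------------------------------------------

def _intercept_results(cls, results_cls, value, structure, n=100):
    """Results object with a forced intercept (for arithmetic checks)."""
    cells = np.ones(n, dtype=int)
    model = cls(cells, const_covariates(n), structure)
    return results_cls(model, np.array([math.log(value)]), -1.0)


class TestOffsets:
    def test_stated_arithmetic(self, common_scenario):
        # p = 1 (huge phi), rho = 200 m -> C = pi 200^2 m^2 = 4 pi ha
        removal = _intercept_results(det.RemovalModel, det.RemovalResults, 1e3, BOUNDARIES)
        distance = _intercept_results(det.DistanceModel, det.DistanceResults, 200.0, EDGES)
        surveys = common_scenario.structured.head(3)
        off = det.compute_offsets(surveys, removal, distance, common_scenario.landscape)
        assert off["p"].to_numpy() == pytest.approx(1.0)
        assert off["C"].to_numpy() == pytest.approx(4 * math.pi)
        assert np.allclose(off["C"], off["area_ha"] * off["p"] * off["q"])

    def test_duration_monotonicity(self, common_scenario):
        removal = _intercept_results(det.RemovalModel, det.RemovalResults, 0.3, BOUNDARIES)
        distance = _intercept_results(det.DistanceModel, det.DistanceResults, 80.0, EDGES)
        surveys = common_scenario.structured.head(2).copy()
        surveys["duration_min"] = [3.0, 30.0]
        off = det.compute_offsets(surveys, removal, distance, common_scenario.landscape)
        ratio = off["C"].iloc[0] / off["C"].iloc[1]
        expected = det.availability(0.3, 3.0) / det.availability(0.3, 30.0)
        assert ratio == pytest.approx(expected) and ratio < 1.0

    def test_fixed_offsets_are_four_pi_hectares(self, common_scenario):
        off = det.fixed_offsets(common_scenario.structured.head(5), radius_m=200.0)
        assert off["C"].to_numpy() == pytest.approx(4 * math.pi)
        assert off["p"].to_numpy() == pytest.approx(1.0)

    def test_offset_identity_recovers_density(self):
        # intercept-only Poisson with log C offset recovers log D within 3 s.e.
        d_true, phi, tau = 2.0, 0.35, 80.0
        rng = np.random.default_rng(1)
        durations = rng.uniform(3, 30, 500)
        counts = syn.simulate_survey_counts(d_true, phi, tau, durations, rng)
        c = math.pi * tau**2 / 1e4 * det.availability(phi, durations)
        fit = sm.GLM(counts, np.ones((500, 1)), family=sm.families.Poisson(),
                     offset=np.log(c)).fit()
        assert abs(fit.params[0] - math.log(d_true)) < 3 * fit.bse[0]

    def test_missing_covariate_column_named_in_error(self):
        model = det.RemovalModel(np.ones(50, dtype=int), const_covariates(50),
                                 BOUNDARIES, terms=("tod",))
        removal = det.RemovalResults(model, np.array([math.log(0.3), 0.0]), -1.0)
        with pytest.raises(InvalidArgumentError, match="min_since_dawn"):
            removal.availability(pd.DataFrame({"jday": [150.0]}), 5.0)
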