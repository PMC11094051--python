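import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from densitycal import synthetic as syn
from densitycal.detection import distance_cell_probs, removal_cell_probs
from densitycal.errors import InvalidArgumentError
from densitycal.landscape import generate_landscape


def flat_truth(density_per_ha=2.0, phi=0.4, tau=80.0, suitable=True):
    """Truth with constant parameters; suitable everywhere (or nowhere)."""
    return syn.SpeciesTruth(
        suit_intercept=10.0 if suitable else -10.0, suit_coefs={},
        suit_threshold=0.5,
        dens_intercept=math.log(density_per_ha) if density_per_ha > 0 else -50.0,
        dens_coefs={}, phi_intercept=math.log(phi),
        tau_intercept=math.log(tau), tau_coefs={})


@pytest.fixture(scope="module")
def small_landscape():
    # 20 x 20 cells of 50 m = 100 ha
    return generate_landscape(20, 20, 50.0, 2, 100.0, seed=0)


# ---------------------------------------------------------------------------
# population realization
# ---------------------------------------------------------------------------

class TestGeneratePopulation:
    def test_zero_density_gives_empty_population(self, small_landscape):
        birds = syn.generate_population(small_landscape, flat_truth(suitable=False), 0)
        assert birds.shape == (0, 2)

    def test_poisson_mean_matches_expected_total(self, small_landscape):
        truth = flat_truth(density_per_ha=2.0)
        counts = [syn.generate_population(small_landscape, truth, s).shape[0]
                  for s in range(200)]
        # 2 birds/ha x 100 ha = 200 expected; mean of 200 draws within 2 s.e.
        se = math.sqrt(200.0 / 200)
        assert abs(np.mean(counts) - 200.0) < 2 * se * math.sqrt(200)

    def test_expected_total_equals_true_population(self, small_landscape):
        truth = flat_truth(density_per_ha=2.0)
        assert truth.true_population(small_landscape) == pytest.approx(200.0)

    def test_birds_fall_inside_suitable_cells(self, small_landscape):
        truth = syn.SpeciesTruth(
            suit_intercept=0.0, suit_coefs={"cov1_165": 4.0}, suit_threshold=0.5,
            dens_intercept=0.0, dens_coefs={}, phi_intercept=math.log(0.4))
        birds = syn.generate_population(small_landscape, truth, 1)
        mask = truth.suitable_mask(small_landscape)
        rows, cols = small_landscape.cell_index(birds[:, 0], birds[:, 1])
        assert mask[rows, cols].all()


# ---------------------------------------------------------------------------
# structured surveys
# ---------------------------------------------------------------------------

class TestStructuredSurvey:
    def test_perfect_detection_limit_detects_all_in_first_interval(self, small_landscape):
        truth = flat_truth(phi=1e4, tau=1e5)
        birds = np.column_stack([np.random.default_rng(0).uniform(400, 600, 20),
                                 np.random.default_rng(1).uniform(400, 600, 20)])
        row, dets = syn.simulate_structured_survey(
            (500.0, 500.0), birds, truth, small_landscape, 150, 100, rng=0)
        assert row["count"] == 20
        assert all(j == 1 for _, j, _ in dets)

    def test_bird_at_zero_distance_always_detected(self, small_landscape):
        truth = flat_truth(phi=1e4, tau=50.0)
        birds = np.array([[500.0, 500.0]])
        for s in range(20):
            row, _ = syn.simulate_structured_survey(
                (500.0, 500.0), birds, truth, small_landscape, 150, 100, rng=s)
            assert row["count"] == 1  # g(0) = 1

    def test_availability_fraction_matches_closed_form(self, small_landscape):
        # phi = 0.5/min over 5 min: availability = 1 - e^{-2.5}
        truth = flat_truth(phi=0.5, tau=1e5)
        birds = np.tile([[500.0, 500.0]], (10_000, 1))
        row, _ = syn.simulate_structured_survey(
            (500.0, 500.0), birds, truth, small_landscape, 150, 100, rng=0)
        frac = row["count"] / 10_000
        assert frac == pytest.approx(1 - math.exp(-2.5), abs=0.015)

    def test_nonpositive_duration_rejected(self, small_landscape):
        with pytest.raises(InvalidArgumentError):
            syn.simulate_structured_survey((500.0, 500.0), np.empty((0, 2)),
                                           flat_truth(), small_landscape, 150, 100,
                                           duration=0.0)

    def test_removal_interval_histogram_matches_cell_probs(self, small_landscape):
        phi = 0.35
        intervals = syn.simulate_removal_sample(phi, 10_000, rng=0)
        probs = removal_cell_probs(phi, [0, 1, 2, 3, 4, 5])
        observed = np.bincount(intervals, minlength=6)[1:]
        p = stats.chisquare(observed, 10_000 * probs).pvalue
        assert p > 0.01

    def test_distance_bin_histogram_matches_half_normal(self, small_landscape):
        tau = 75.0
        bins = syn.simulate_distance_sample(tau, 10_000, rng=0)
        probs = distance_cell_probs(tau, syn.DEFAULT_BIN_EDGES_M)
        observed = np.bincount(bins, minlength=6)[1:]
        p = stats.chisquare(observed, 10_000 * probs).pvalue
        assert p > 0.01

    def test_detected_count_expectation_identity(self):
        # E[Y] = D x (pi tau^2 / 1e4) x (1 - e^{-phi T})
        d, phi, tau, t = 5.0, 0.4, 80.0, 5.0
        counts = syn.simulate_survey_counts(d, phi, tau, np.full(2000, t), rng=0)
        expected = d * math.pi * tau**2 / 1e4 * (1 - math.exp(-phi * t))
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# community checklists
# ---------------------------------------------------------------------------

class TestCommunityChecklists:
    def test_matched_observers_match_structured_counts(self, small_landscape):
        truth = flat_truth(density_per_ha=8.0)
        birds = syn.generate_population(small_landscape, truth, 0)
        matched = [syn.ObserverProfile("o1")]
        comm = syn.simulate_community_checklists(
            small_landscape, birds, truth, matched, 400,
            hotspot_fraction=0.0, duration_range=(5.0, 5.0), seed=1,
            protocol_probs=(1.0, 0.0, 0.0), complete_prob=1.0, margin_m=250.0)
        struct, _ = syn.simulate_structured_surveys(
            small_landscape, truth, birds, 400, seed=2, margin_m=250.0)
        m1, m2 = comm["count"].mean(), struct["count"].mean()
        se = math.sqrt(comm["count"].var() / 400 + struct["count"].var() / 400)
        assert abs(m1 - m2) < 3 * se

    def test_x_probability_one_makes_all_positives_presence_only(self, small_landscape):
        truth = flat_truth(density_per_ha=8.0)
        birds = syn.generate_population(small_landscape, truth, 0)
        obs = [syn.ObserverProfile("o1", x_prob=1.0)]
        comm = syn.simulate_community_checklists(
            small_landscape, birds, truth, obs, 200, seed=3)
        positives = comm["count"] > 0
        assert not positives.any()  # every positive became "X"
        assert comm["is_x"].sum() > 0

    def test_halving_kappa_quarters_mean_count(self, small_landscape):
        # effective area scales as (kappa tau)^2
        truth = flat_truth(density_per_ha=10.0, phi=5.0, tau=60.0)
        birds = syn.generate_population(small_landscape, truth, 0)
        kw = dict(hotspot_fraction=0.0, duration_range=(5.0, 5.0),
                  protocol_probs=(1.0, 0.0, 0.0), complete_prob=1.0)
        full = syn.simulate_community_checklists(
            small_landscape, birds, truth, [syn.ObserverProfile("a", kappa=1.0)],
            1000, seed=4, **kw)
        half = syn.simulate_community_checklists(
            small_landscape, birds, truth, [syn.ObserverProfile("b", kappa=0.5)],
            1000, seed=5, **kw)
        ratio = half["count"].mean() / full["count"].mean()
        assert ratio == pytest.approx(0.25, abs=0.05)

    def test_invalid_hotspot_fraction_rejected(self, small_landscape):
        with pytest.raises(InvalidArgumentError):
            syn.simulate_community_checklists(
                small_landscape, np.empty((0, 2)), flat_truth(),
                [syn.ObserverProfile("o1")], 10, hotspot_fraction=1.5, seed=0)

    def test_empty_observers_rejected(self, small_landscape):
        with pytest.raises(InvalidArgumentError):
            syn.simulate_community_checklists(
                small_landscape, np.empty((0, 2)), flat_truth(), [], 10, seed=0)


# ---------------------------------------------------------------------------
# fixture scenarios
# ---------------------------------------------------------------------------

class TestScenarios:
    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            syn.make_fixture_scenario("mystery", 0)

    def test_same_name_and_seed_reproduce_identical_bundles(self):
        a = syn.make_fixture_scenario("uncommon", 11, n_structured=60, n_community=80)
        b = syn.make_fixture_scenario("uncommon", 11, n_structured=60, n_community=80)
        pd.testing.assert_frame_equal(a.structured, b.structured)
        pd.testing.assert_frame_equal(a.community, b.community)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        np.testing.assert_array_equal(a.birds, b.birds)

    def test_common_scenario_prevalence_in_range(self, common_scenario):
        prev = (common_scenario.structured["count"] > 0).mean()
        assert 0.3 <= prev <= 0.6

    def test_rare_scenario_has_few_positive_structured_surveys(self):
        sc = syn.make_fixture_scenario("rare", 5)
        assert (sc.structured["count"] > 0).sum() < 60

    def test_aurally_cryptic_community_counts_biased_low(self):
        sc = syn.make_fixture_scenario("aurally_cryptic", 5, n_structured=50,
                                       n_community=400)
        matched = syn.make_fixture_scenario("common", 5, n_structured=50,
                                            n_community=400)
        assert sc.community["count"].mean() < matched.community["count"].mean()

    def test_observer_identity_invariant(self):
        obs = syn.ObserverProfile("o", kappa=1.0, thinning=1.0, x_prob=0.0)
        assert obs.kappa == 1.0 and obs.thinning == 1.0 and obs.x_prob == 0.0
        with pytest.raises(InvalidArgumentError):
            syn.ObserverProfile("bad", kappa=0.0)
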