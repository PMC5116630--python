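"""Unit and property tests for the analytic whole-report score model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from tvawr import (
    TVAParams,
    conditional_score_pmf,
    expected_K,
    expected_score,
    item_rate,
    log_likelihood,
    marginal_item_encoding_prob,
    score_pmf,
    simulate_scores,
)
from tvawr.model import N_ITEMS, TrialRecord

from conftest import random_params


def make_trial(exposure_ms, n_correct, **kw):
    defaults = dict(
        participant_id="p", device="CRT", session=1, block=1, trial_index=1,
        exposure_ms=exposure_ms, n_correct=n_correct,
    )
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestItemRate:
    @pytest.mark.parametrize(
        "C, n_items, expected",
        [(60.0, 6, 0.01), (81.17, 6, 0.0135283333), (100.0, 1, 0.1)],
    )
    def test_equal_weight_rate(self, C, n_items, expected):
        params = TVAParams(t0_mean=10, t0_sd=1, C=C)
        assert item_rate(params, n_items) == pytest.approx(expected, rel=1e-6)

    def test_invalid_n_items(self):
        with pytest.raises(ValueError):
            item_rate(TVAParams(10, 1, 50), 0)


class TestConditionalScorePmf:
    def test_exposure_below_threshold_gives_zero_score(self, reference_params):
        d = conditional_score_pmf(reference_params, 10.0, 15.0)
        assert d[0] == pytest.approx(1.0)

    def test_unlimited_capacity_certain_encoding(self):
        params = TVAParams(t0_mean=0, t0_sd=0, C=600, k_probs=[0, 0, 0, 0, 0, 1])
        d = conditional_score_pmf(params, 1e5, 0.0)
        assert d[6] == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """Brute-force sum over every (item-finished pattern, capacity) outcome."""
        params = TVAParams(t0_mean=0, t0_sd=0, C=60.0)  # uniform k_probs
        tau = 100.0
        F = 1.0 - np.exp(-item_rate(params) * tau)
        oracle = np.zeros(N_ITEMS + 1)
        for pattern in itertools.product([0, 1], repeat=N_ITEMS):
            b = sum(pattern)
            p_pattern = F**b * (1 - F) ** (N_ITEMS - b)
            for k in range(1, N_ITEMS + 1):
                oracle[min(k, b)] += p_pattern / N_ITEMS
        d = conditional_score_pmf(params, tau, 0.0)
        np.testing.assert_allclose(d.probs, oracle, atol=1e-12)


class TestScorePmf:
    def test_degenerate_normal_equals_conditional(self, reference_params):
        params = TVAParams(14.0, 0.0, 80.0, reference_params.k_probs)
        marginal = score_pmf(params, 53.0)
        conditional = conditional_score_pmf(params, 53.0, 14.0)
        np.testing.assert_allclose(marginal.probs, conditional.probs, atol=1e-12)

    def test_matches_monte_carlo(self, reference_params, rng):
        """Quadrature vs the race simulator at several exposures."""
        n = 400_000
        for exposure in (20.0, 53.0, 140.0):
            analytic = score_pmf(reference_params, exposure).probs
            emp = np.bincount(
                simulate_scores(reference_params, exposure, n, rng), minlength=7
            ) / n
            se = np.sqrt(analytic * (1 - analytic) / n)
            assert np.all(np.abs(emp - analytic) <= 3 * se + 1e-9)

    def test_long_exposure_recovers_capacity_distribution(self, reference_params):
        d = score_pmf(reference_params, 1e5)
        np.testing.assert_allclose(d.probs[1:], reference_params.k_probs, atol=1e-9)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_classic_exponential_race_limit(self):
        """Hard threshold and capacity 6: the score is Binomial(6, 1-e^{-v tau})."""
        params = TVAParams(t0_mean=12.0, t0_sd=0.0, C=90.0, k_probs=[0, 0, 0, 0, 0, 1])
        for exposure in (20.0, 60.0, 150.0):
            tau = exposure - 12.0
            F = 1.0 - np.exp(-item_rate(params) * tau)
            closed_form = stats.binom.pmf(np.arange(7), N_ITEMS, F)
            np.testing.assert_allclose(score_pmf(params, exposure).probs, closed_form, atol=1e-12)

    def test_needs_enough_nodes(self, reference_params):
        with pytest.raises(ValueError):
            score_pmf(reference_params, 50.0, n_nodes=4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), exposure=st.floats(1.0, 300.0))
    def test_pmf_is_normalized(self, seed, exposure):
        params = random_params(np.random.default_rng(seed))
        d = score_pmf(params, exposure)
        assert np.all(d.probs >= 0)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-8)


class TestMarginalItemEncodingProb:
    def test_hard_threshold_zero_exposure(self):
        params = TVAParams(t0_mean=20.0, t0_sd=0.0, C=80.0)
        assert marginal_item_encoding_prob(params, 20.0) == 0.0

    def test_hard_threshold_exponential_median(self):
        # v * (t - mu) = ln 2 at the exponential median
        params = TVAParams(t0_mean=10.0, t0_sd=0.0, C=60.0)
        t = 10.0 + np.log(2) / item_rate(params)
        assert marginal_item_encoding_prob(params, t) == pytest.approx(0.5, abs=1e-12)

    def test_matches_numeric_convolution(self, reference_params):
        v = item_rate(reference_params)
        f = lambda t0: stats.norm.pdf(t0, 14.0, 5.0) * -np.expm1(-v * max(80.0 - t0, 0.0))
        oracle, _ = integrate.quad(f, 14.0 - 10 * 5.0, 80.0)
        assert marginal_item_encoding_prob(reference_params, 80.0) == pytest.approx(
            oracle, abs=1e-3
        )

    def test_consistency_with_score_pmf_at_full_capacity(self):
        """With capacity pinned at 6 the mean score is 6x the per-item
        encoding probability (items are exchangeable)."""
        params = TVAParams(t0_mean=14.0, t0_sd=5.0, C=80.0, k_probs=[0, 0, 0, 0, 0, 1])
        for exposure in (30.0, 80.0, 160.0):
            assert expected_score(params, exposure, n_nodes=128) / N_ITEMS == pytest.approx(
                marginal_item_encoding_prob(params, exposure), abs=1e-5
            )


class TestExpectedValues:
    @pytest.mark.parametrize(
        "k_probs, expected",
        [
            (np.full(6, 1 / 6), 3.5),
            ([0, 0, 0, 0, 0, 1], 6.0),
            ((0.05, 0.10, 0.20, 0.30, 0.25, 0.10), 3.9),
        ],
    )
    def test_expected_K(self, k_probs, expected):
        assert expected_K(k_probs) == pytest.approx(expected)

    def test_expected_K_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            expected_K([0.5, 0.5, 0.5, 0, 0, 0])

    def test_expected_score_limits(self, reference_params):
        low = TVAParams(t0_mean=50.0, t0_sd=0.5, C=80.0)
        assert expected_score(low, 10.0) == pytest.approx(0.0, abs=1e-6)
        assert expected_score(reference_params, 1e5) == pytest.approx(3.9, abs=1e-6)

    def test_expected_score_monotone_in_exposure_and_speed(self, reference_params):
        exposures = np.linspace(5, 250, 30)
        means = [expected_score(reference_params, e) for e in exposures]
        assert np.all(np.diff(means) >= -1e-10)
        speeds = [expected_score(TVAParams(14, 5, C, reference_params.k_probs), 60.0)
                  for C in (20, 50, 80, 120, 200)]
        assert np.all(np.diff(speeds) >= -1e-10)

    def test_stochastic_dominance_of_capacity(self):
        """Shifting capacity mass upward cannot lower the mean score."""
        lo = TVAParams(14, 5, 80, [0.4, 0.3, 0.2, 0.1, 0.0, 0.0])
        hi = TVAParams(14, 5, 80, [0.0, 0.1, 0.2, 0.3, 0.2, 0.2])
        for exposure in (30.0, 80.0, 200.0):
            assert expected_score(hi, exposure) >= expected_score(lo, exposure)


class TestLogLikelihood:
    def test_certain_zero_score_has_zero_loglik(self):
        params = TVAParams(t0_mean=100.0, t0_sd=0.0, C=80.0)
        trial = make_trial(exposure_ms=10.0, n_correct=0)
        assert log_likelihood(params, [trial]) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_duplicated_trials(self, reference_params):
        trial = make_trial(exposure_ms=53.0, n_correct=3)
        single = log_likelihood(reference_params, [trial])
        assert log_likelihood(reference_params, [trial] * 10) == pytest.approx(10 * single)

    def test_matches_per_trial_pmf_lookup(self, reference_params):
        toy = [
            make_trial(10.0, 0), make_trial(20.0, 1), make_trial(53.0, 2),
            make_trial(80.0, 4), make_trial(147.0, 3), make_trial(200.0, 6),
        ]
        oracle = sum(
            np.log(score_pmf(reference_params, t.exposure_ms)[t.n_correct]) for t in toy
        )
        assert log_likelihood(reference_params, toy) == pytest.approx(oracle, rel=1e-12)

    def test_empty_trials_rejected(self, reference_params):
        with pytest.raises(ValueError):
            log_likelihood(reference_params, [])

    def test_finite_for_impossible_data(self):
        # score 6 at an exposure the model deems (numerically) impossible
        params = TVAParams(t0_mean=150.0, t0_sd=0.01, C=5.0)
        ll = log_likelihood(params, [make_trial(10.0, 6)])
        assert np.isfinite(ll) and ll < -100


class TestTrialRecordValidation:
    def test_rejects_inconsistent_report_counts(self):
        with pytest.raises(ValueError):
            make_trial(50.0, 2, reported_letters="ABD", n_errors=0)

    def test_rejects_duplicate_letters(self):
        with pytest.raises(ValueError):
            make_trial(50.0, 0, displayed_letters="AABDEF")

    def test_rejects_out_of_set_letters(self):
        with pytest.raises(ValueError):
            make_trial(50.0, 0, displayed_letters="ABDEFC")  # C not in the stimulus set
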