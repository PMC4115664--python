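"""Excess-significance binomial test and the power model behind it."""

import math

import numpy as np
import pytest
from scipy import stats

from metabias import (
    SampleSizeLaw,
    SimulationConfig,
    StudyValidationError,
    excess_significance_test,
    fixed_effect,
    simulate_literature,
    study_power,
)
from metabias.excess_significance import _poisson_binomial_sf

from conftest import toy_sample


class TestStudyPower:
    def test_null_effect_gives_alpha_exactly(self):
        assert study_power(0.0, 27, 27, alpha=0.05) == pytest.approx(0.05, abs=1e-12)

    def test_limit_to_one(self):
        assert study_power(10.0, 27, 27) == pytest.approx(1.0, abs=1e-12)

    def test_against_monte_carlo_two_group_experiments(self):
        # Oracle: simulate experiments and count two-sided rejections.  The
        # package's power model uses the null-variance SE, so agreement is
        # to ~0.02, not exact.
        rng = np.random.default_rng(2024)
        n, delta, reps = 27, 0.62, 200_000
        xt = rng.normal(delta, 1.0, (reps, n))
        xc = rng.normal(0.0, 1.0, (reps, n))
        s2 = (xt.var(axis=1, ddof=1) + xc.var(axis=1, ddof=1)) / 2
        d = (xt.mean(axis=1) - xc.mean(axis=1)) / np.sqrt(s2)
        v = 2 / n + d**2 / (4 * n)
        mc_power = np.mean(2 * stats.norm.sf(np.abs(d) / np.sqrt(v)) < 0.05)
        assert study_power(delta, n, n) == pytest.approx(mc_power, abs=0.02)

    def test_monotone_in_effect_size(self):
        powers = [study_power(d, 27, 27) for d in np.linspace(0, 1.5, 25)]
        assert all(b > a for a, b in zip(powers, powers[1:]))


class TestExcessSignificanceTest:
    def test_exact_enumeration_example(self):
        # k=10, all power 0.5, 8 observed significant: P(X>=8) = 56/1024
        assert stats.binom.sf(7, 10, 0.5) == pytest.approx(56 / 1024, rel=1e-12)
        sample = toy_sample([3.0] * 8 + [0.0] * 2, 0.04, alpha=0.05)
        res = excess_significance_test(sample, basis="individual")
        assert res.observed_sig == 8

    def test_zero_observed_boundary(self):
        sample = toy_sample([0.01, -0.02, 0.03], 0.04)
        res = excess_significance_test(sample, basis="individual")
        assert res.observed_sig == 0
        assert res.binom_p == 1.0

    def test_binomial_p_matches_hand_formula(self, censored_fixture):
        res = excess_significance_test(censored_fixture, basis="fixed")
        assert res.binom_p == pytest.approx(
            stats.binom.sf(res.observed_sig - 1, res.k, res.mean_power), rel=1e-12
        )
        assert res.expected_sig == pytest.approx(res.k * res.mean_power, rel=1e-12)

    def test_fixed_basis_uses_pooled_estimate(self, censored_fixture):
        res = excess_significance_test(censored_fixture, basis="fixed")
        theta = fixed_effect(censored_fixture).theta
        i = 4
        s = censored_fixture.studies[i]
        assert res.per_study_power[i] == pytest.approx(
            study_power(theta, s.n_treat, s.n_ctrl), rel=1e-12
        )

    def test_individual_basis_uses_each_study_d(self, censored_fixture):
        res = excess_significance_test(censored_fixture, basis="individual")
        for s, p in zip(censored_fixture.studies, res.per_study_power):
            assert p == pytest.approx(study_power(s.d, s.n_treat, s.n_ctrl), rel=1e-12)

    def test_mean_power_increasing_in_assumed_effect(self):
        sample = toy_sample([0.3, 0.5, 0.2, 0.4], 0.05)
        # same sample, growing |assumed effect| via the individual basis
        smaller = excess_significance_test(sample, basis="individual").mean_power
        bigger = excess_significance_test(
            toy_sample([0.6, 1.0, 0.4, 0.8], 0.05), basis="individual"
        ).mean_power
        assert bigger > smaller

    def test_binom_p_weakly_decreasing_in_observed(self):
        for k, p in [(10, 0.4), (30, 0.6)]:
            tails = [stats.binom.sf(o - 1, k, p) for o in range(k + 1)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_poisson_binomial_matches_enumeration(self):
        probs = np.array([0.2, 0.5, 0.7])
        # exact enumeration over the 2^3 outcomes
        exact = 0.0
        for mask in range(8):
            bits = [(mask >> j) & 1 for j in range(3)]
            if sum(bits) >= 2:
                pr = 1.0
                for b, p in zip(bits, probs):
                    pr *= p if b else 1 - p
                exact += pr
        assert _poisson_binomial_sf(2, probs) == pytest.approx(exact, rel=1e-12)

    def test_poisson_binomial_flag_changes_reference(self, censored_fixture):
        plain = excess_significance_test(censored_fixture, basis="individual")
        pb = excess_significance_test(
            censored_fixture, basis="individual", poisson_binomial=True
        )
        assert pb.binom_p != plain.binom_p  # heterogeneous powers

    def test_unknown_basis(self, censored_fixture):
        with pytest.raises(StudyValidationError):
            excess_significance_test(censored_fixture, basis="bogus")


class TestCalibrationWithoutCensoring:
    def test_rejection_rate_near_nominal_never_anticonservative(self):
        """On uncensored literatures with the true effect as the assumed
        effect, the one-tailed binomial test should reject at about the
        nominal rate - slightly below it, because the binomial is discrete
        and the power model uses the null-variance SE."""
        rng_seed = 77
        reps, k, delta, alpha = 5000, 40, 0.4, 0.05
        law = SampleSizeLaw()
        rejections = 0
        rng = np.random.default_rng(rng_seed)
        for r in range(reps):
            cfg = SimulationConfig(
                delta_true=delta,
                k_published=k,
                publish_prob_nonsig=1.0,  # no censoring
                n_dist=law,
                seed=int(rng.integers(2**31)),
            )
            lit = simulate_literature(cfg)
            # vectorized equivalent of study_power over the sample
            n1, n2 = lit.published.n_treat, lit.published.n_ctrl
            se0 = np.sqrt((n1 + n2) / (n1 * n2))
            zc = stats.norm.ppf(1 - alpha / 2)
            powers = stats.norm.sf(zc - delta / se0) + stats.norm.cdf(-zc - delta / se0)
            if r == 0:
                s0 = lit.published.studies[0]
                assert powers[0] == pytest.approx(
                    study_power(delta, s0.n_treat, s0.n_ctrl), rel=1e-12
                )
            observed = lit.published.significant_count
            p = stats.binom.sf(observed - 1, k, powers.mean())
            rejections += p < alpha
        rate = rejections / reps
        mc3 = 3 * math.sqrt(alpha * (1 - alpha) / reps)
        assert rate < alpha + mc3  # never anticonservative
        assert rate > 0.01  # and not degenerately conservative
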