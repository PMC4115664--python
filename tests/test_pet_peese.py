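"""WLS regressions (PET/PEESE), Egger equivalence, conditional estimator.

Frozen oracle values were computed with R's lm() (weighted, multiplicative
dispersion) on the fixture tables; the in-test oracles are statsmodels WLS
and an independently coded classical Egger regression.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabias import (
    SimulationConfig,
    StudyValidationError,
    peese,
    pet,
    pet_peese,
    simulate_literature,
    wls_fit,
)
from metabias.pet_peese import significance_stars

from conftest import random_sample, toy_sample


class TestWlsFit:
    def test_exact_line_is_interpolated(self):
        se = np.array([0.1, 0.2, 0.3, 0.4])
        y = 0.1 + 2.0 * se
        res = wls_fit(y, se, 1 / se**2)
        assert res.b0 == pytest.approx(0.1, abs=1e-12)
        assert res.b1 == pytest.approx(2.0, abs=1e-12)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_equal_weights_reduce_to_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.3, 0.9, 0.8, 1.6])
        res = wls_fit(y, x, np.ones(4))
        # textbook closed form
        b1 = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        b0 = y.mean() - b1 * x.mean()
        assert res.b0 == pytest.approx(b0, rel=1e-12)
        assert res.b1 == pytest.approx(b1, rel=1e-12)

    def test_against_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        for _ in range(10):
            k = 10
            x = rng.uniform(0.05, 0.5, k)
            y = 0.2 + 1.5 * x + rng.normal(0, 0.1, k)
            w = 1 / x**2
            mine = wls_fit(y, x, w)
            ref = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert mine.b0 == pytest.approx(ref.params[0], abs=1e-10)
            assert mine.b1 == pytest.approx(ref.params[1], abs=1e-10)
            assert mine.se_b0 == pytest.approx(ref.bse[0], abs=1e-10)
            assert mine.p_b1 == pytest.approx(ref.pvalues[1], abs=1e-10)
            ci = ref.conf_int()
            assert mine.ci_b0 == pytest.approx(tuple(ci[0]), abs=1e-10)
            assert mine.ci_b1 == pytest.approx(tuple(ci[1]), abs=1e-10)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_weight_scale_equivariance(self, scale):
        x = np.array([0.1, 0.25, 0.3, 0.45, 0.5])
        y = np.array([0.5, 0.4, 0.7, 0.9, 0.6])
        w = 1 / x**2
        a = wls_fit(y, x, w)
        b = wls_fit(y, x, w * scale)
        assert a.b0 == pytest.approx(b.b0, rel=1e-11)
        assert a.se_b0 == pytest.approx(b.se_b0, rel=1e-9)
        assert a.ci_b1 == pytest.approx(b.ci_b1, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(StudyValidationError, match="constant"):
            wls_fit(np.array([1.0, 2, 3]), np.full(3, 0.2), np.ones(3))

    def test_too_few_points_rejected(self):
        with pytest.raises(StudyValidationError):
            wls_fit(np.array([1.0, 2]), np.array([0.1, 0.2]), np.ones(2))


class TestPetPeeseModels:
    def test_pet_against_frozen_lm(self, censored_fixture):
        res = pet(censored_fixture)
        assert res.b0 == pytest.approx(-0.9646309177, abs=1e-9)
        assert res.ci_b0 == pytest.approx((-1.7569636214, -0.1722982141), abs=1e-8)
        assert res.b1 == pytest.approx(4.0947580001, abs=1e-9)
        assert res.t_b1 == pytest.approx(3.2982653744, abs=1e-8)
        assert res.p_b1 == pytest.approx(0.005766933589, rel=1e-7)
        assert res.asymmetry_significant()

    def test_peese_against_frozen_lm(self, censored_fixture):
        res = peese(censored_fixture)
        assert res.b0 == pytest.approx(-0.2810239057, abs=1e-9)
        assert res.ci_b0 == pytest.approx((-0.6558359775, 0.0937881662), abs=1e-8)
        assert res.b1 == pytest.approx(5.7996680738, abs=1e-8)

    def test_pet_slope_equals_classical_egger(self):
        """Independent oracle: the classical Egger test regresses z_i on
        precision 1/se_i by OLS; its intercept is algebraically PET's
        slope, with the same t and p."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            s = random_sample(rng, k=12)
            res = pet(s)
            z = s.d / s.se
            prec = 1.0 / s.se
            X = np.column_stack([np.ones(s.k), prec])
            b, (rss,), *_ = np.linalg.lstsq(X, z, rcond=None)
            sigma2 = rss / (s.k - 2)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            t_egger = b[0] / np.sqrt(cov[0, 0])
            p_egger = 2 * stats.t.sf(abs(t_egger), s.k - 2)
            assert res.b1 == pytest.approx(b[0], rel=1e-9)
            assert res.t_b1 == pytest.approx(t_egger, rel=1e-9)
            assert res.p_b1 == pytest.approx(p_egger, rel=1e-9)

    def test_constant_effect_flat_peese(self):
        s = toy_sample([0.3, 0.3, 0.3, 0.3], [0.01, 0.04, 0.09, 0.16])
        res = peese(s)
        assert res.b0 == pytest.approx(0.3, abs=1e-12)
        assert res.b1 == pytest.approx(0.0, abs=1e-10)


class TestConditionalEstimator:
    def test_branch_invariant(self, censored_fixture, homogeneous_fixture):
        for sample in (censored_fixture, homogeneous_fixture):
            cond = pet_peese(sample)
            assert (cond.chosen_model == "PEESE") == (cond.pet.p_b0 < 0.05)

    def test_exact_line_nonzero_intercept_takes_peese(self):
        se = np.array([0.1, 0.2, 0.3])
        s = toy_sample(list(0.4 + 1.0 * se), list(se**2))
        cond = pet_peese(s)
        assert cond.pet.p_b0 < 1e-8  # interpolated, dispersion ~ 0
        assert cond.chosen_model == "PEESE"

    def test_symmetric_unbiased_simulation_keeps_truth_in_pet_ci(self):
        """Without censoring and with a real effect, PET's CI should cover
        the truth most of the time."""
        delta, reps = 0.5, 40
        covered = 0
        for seed in range(reps):
            lit = simulate_literature(
                SimulationConfig(
                    delta_true=delta, k_published=80, publish_prob_nonsig=1.0, seed=seed
                )
            )
            cond = pet_peese(lit.published)
            covered += cond.pet.ci_b0[0] <= delta <= cond.pet.ci_b0[1]
        assert covered >= reps * 0.8

    def test_strong_effect_without_censoring_takes_peese_branch(self):
        """A strong, uncensored effect makes PET reject b0 = 0, so the
        conditional estimator should nearly always hand over to PEESE and
        land near the truth (PEESE inherits a mild downward pull from the
        mechanical d-variance coupling, so 'near' is ~15-20%)."""
        delta, reps = 0.8, 40
        chose_peese = 0
        finals = []
        for seed in range(reps):
            lit = simulate_literature(
                SimulationConfig(
                    delta_true=delta, k_published=150, publish_prob_nonsig=1.0, seed=seed
                )
            )
            cond = pet_peese(lit.published)
            chose_peese += cond.chosen_model == "PEESE"
            finals.append(cond.final_b0)
        assert chose_peese >= reps * 0.85
        assert 0.75 * delta < np.mean(finals) < 1.1 * delta

    def test_peese_beats_pet_for_nonzero_effect_under_censoring(self):
        """The crossover that motivates the conditional rule: with a real
        effect and moderate censoring, PET over-corrects (underestimates)
        while PEESE stays closer to the truth."""
        delta, reps = 0.5, 30
        pet_b0, peese_b0 = [], []
        for seed in range(reps):
            lit = simulate_literature(
                SimulationConfig(
                    delta_true=delta, k_published=150, publish_prob_nonsig=0.5, seed=seed
                )
            )
            cond = pet_peese(lit.published)
            pet_b0.append(cond.pet.b0)
            peese_b0.append(cond.peese.b0)
        assert abs(np.mean(peese_b0) - delta) < abs(np.mean(pet_b0) - delta)
        assert np.mean(pet_b0) < delta  # over-correction direction

    def test_one_tailed_branch_requires_positive_intercept(self, censored_fixture):
        # censored fixture: PET b0 is significantly *negative*, so the
        # one-tailed (positive) branch must stay with PET
        two = pet_peese(censored_fixture)
        one = pet_peese(censored_fixture, one_tailed=True)
        assert two.chosen_model == "PEESE"
        assert one.chosen_model == "PET"


def test_significance_stars_thresholds():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.07, 0.5)] == [
        "***",
        "**",
        "*",
        "†",
        "",
    ]
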