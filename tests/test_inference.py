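"""Tests for likelihood, fitting, prediction and the distribution analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormrepro.inference import (
    cov,
    fit_brood_mixture,
    fit_mle,
    fit_temperature_law,
    infer_sperm_from_brood,
    negloglik_timecourse,
    permutation_test_cov,
    predict_cohort,
    FitResult,
)
from wormrepro.kinetics import KineticParams, TemperatureLaw, egg_curve
from wormrepro.simulate import ObservationProtocol, PopulationParams, simulate_cohort_at_params


class TestLikelihood:
    def test_truth_beats_perturbed_capacity(self, pp, cohort20):
        nll_true = negloglik_timecourse(cohort20, {"mu_kmax": 10.0, "k_d": 1e-3}, pp)
        nll_pert = negloglik_timecourse(cohort20, {"mu_kmax": 20.0, "k_d": 1e-3}, pp)
        assert nll_true < nll_pert

    def test_profile_minimum_near_truth(self, pp, cohort20):
        """The likelihood profile over capacity dips at the generating value."""
        grid = [6.0, 10.0, 16.0]
        nll = [negloglik_timecourse(cohort20, {"mu_kmax": k, "k_d": 1e-3}, pp) for k in grid]
        assert nll[1] < nll[0] and nll[1] < nll[2]

    def test_empty_table_rejected(self, pp):
        with pytest.raises(ValueError):
            negloglik_timecourse(pd.DataFrame(columns=["temp_C"]), {"mu_kmax": 10, "k_d": 0}, pp)

    def test_variance_collapse_takes_penalty_path(self, cohort20):
        """With no heterogeneity the model variance collapses to the floor and
        data off the deterministic curve are heavily penalized, not -inf."""
        pp0 = PopulationParams(sigma_S=0, sigma_t0=0, sigma_kmax=0)
        nll = negloglik_timecourse(cohort20, {"mu_kmax": 3.0, "k_d": 0.5}, pp0)
        assert np.isfinite(nll) and nll > 1e5

    def test_invalid_candidate_penalized(self, pp, cohort20):
        assert negloglik_timecourse(cohort20, {"mu_kmax": -1, "k_d": 0}, pp) == 1e10


class TestFitMLE:
    def test_deterministic_limit_identifiability(self):
        """With heterogeneity switched off, (k_max, k_d) are recovered to ~1%."""
        pp0 = PopulationParams(sigma_S=0, sigma_t0=0, sigma_kmax=0)
        p = KineticParams.from_qss(12.0, 100.0, 0.05)
        proto = ObservationProtocol(n_longitudinal=12, n_per_dense_timepoint=2)
        tab = simulate_cohort_at_params(pp0, p, 0.0, proto, T=25.0, seed=0)
        fr = fit_mle(tab, 25.0, pp0, n_starts=4, seed=1, fit_delta=False)
        assert fr.estimates["mu_kmax"] == pytest.approx(12.0, rel=0.01)
        assert fr.estimates["k_d"] == pytest.approx(0.05, rel=0.01)

    def test_degenerate_table_rejected(self, pp, cohort20):
        tiny = cohort20[cohort20["individual_id"] == cohort20["individual_id"].iloc[0]]
        with pytest.raises(ValueError):
            fit_mle(tiny, 20.0, pp)

    def test_delta_fixed_at_permissive_temperatures(self, pp, cohort20):
        fr = fit_mle(cohort20, 20.0, pp, n_starts=2, seed=0)
        assert fr.estimates["delta"] == 0.0


class TestTemperatureLawFit:
    def _fits(self, values):
        return {
            T: FitResult(estimates=est, loglik=0.0, temp_C=T, converged=True,
                         n_starts=1, seed=0)
            for T, est in values.items()
        }

    def test_exact_exponential_recovered(self):
        truth_a, truth_b = -2.0, 0.1
        fits = self._fits({
            T: {"mu_kmax": np.exp(truth_a + truth_b * T), "k_d": 1e-3, "delta": 0.0}
            for T in (20.0, 25.0, 29.0)
        })
        law = fit_temperature_law(fits)
        a, b = law.coef["k_max"]
        assert a == pytest.approx(truth_a, abs=1e-9) and b == pytest.approx(truth_b, abs=1e-10)

    def test_constant_parameter_gives_zero_slope(self):
        fits = self._fits({T: {"mu_kmax": 5.0, "k_d": 0.01} for T in (20.0, 25.0, 29.0)})
        assert fit_temperature_law(fits).coef["k_max"][1] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_estimates_excluded_with_warning(self):
        fits = self._fits({
            20.0: {"mu_kmax": 10.0, "delta": 0.0},
            28.0: {"mu_kmax": 12.0, "delta": 0.3},
            29.0: {"mu_kmax": 13.0, "delta": 0.6},
        })
        with pytest.warns(UserWarning, match="non-positive"):
            law = fit_temperature_law(fits)
        # delta law from the two usable points only
        assert law.delta_at(28.0) == pytest.approx(0.3, rel=1e-6)
        assert law.delta_at(29.0) == pytest.approx(0.6, rel=1e-6)

    def test_single_temperature_degrades_to_flat_law(self):
        fits = self._fits({25.0: {"mu_kmax": 10.0}})
        with pytest.warns(UserWarning, match="single temperature"):
            law = fit_temperature_law(fits)
        assert law.coef["k_max"][1] == 0.0


class TestPredictCohort:
    LAW = TemperatureLaw(
        coef={"k_max": (np.log(10.0) - 20 * 0.045, 0.045),
              "k_d": (np.log(1e-3) - 20 * 0.61, 0.61),
              "delta": (np.log(0.3) - 28 * 0.693, 0.693)},
    )

    def test_median_tracks_generating_curve(self, pp):
        proto = ObservationProtocol()
        pred = predict_cohort(self.LAW, pp, 25.0, proto, n_rep=400, seed=0)
        # deterministic reference animal at the population means
        from wormrepro.kinetics import params_at_temperature

        p, _ = params_at_temperature(25.0, self.LAW)
        ref = egg_curve(proto.all_times, p.k_max, p.k_hat, p.k_d, pp.mu_S, pp.mu_t0)
        late = proto.all_times > 24
        assert np.allclose(pred["median"][late], ref[late], rtol=0.1)

    def test_bands_widen_with_capacity_spread(self, pp):
        proto = ObservationProtocol()
        wide = PopulationParams(**{**pp.__dict__, "sigma_kmax": 3.0})
        sd_narrow = predict_cohort(self.LAW, pp, 25.0, proto, n_rep=300, seed=1)["sd"]
        sd_wide = predict_cohort(self.LAW, wide, 25.0, proto, n_rep=300, seed=1)["sd"]
        mid = (proto.all_times > 4) & (proto.all_times < 24)
        assert np.all(sd_wide[mid.to_numpy() if hasattr(mid, "to_numpy") else mid]
                      > sd_narrow[mid])

    def test_reproduction_ceases_at_thirty_degrees(self, pp):
        """A steep δ law puts nearly every animal in the failing class at 30 °C."""
        proto = ObservationProtocol()
        pred = predict_cohort(self.LAW, pp, 30.0, proto, n_rep=300, seed=2)
        final_mean = pred["mean"].iloc[-1]
        pred20 = predict_cohort(self.LAW, pp, 20.0, proto, n_rep=300, seed=2)
        assert final_mean < 0.2 * pred20["mean"].iloc[-1]


class TestSpermInference:
    def test_identical_broods(self):
        mu, sd = infer_sperm_from_brood([300.0] * 10)
        assert (mu, sd) == (300.0, 0.0)

    def test_sample_moments(self):
        rng = np.random.default_rng(0)
        broods = rng.normal(437, 40, size=2000)
        mu, sd = infer_sperm_from_brood(broods)
        assert mu == pytest.approx(broods.mean()) and sd == pytest.approx(broods.std(ddof=1))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            infer_sperm_from_brood([300.0])


class TestCov:
    def test_hand_computed(self):
        assert cov([100.0, 200.0, 300.0]) == pytest.approx(0.5)

    def test_constant_sample(self):
        assert cov([5.0, 5.0, 5.0]) == 0.0

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        x = np.array([100.0, 150.0, 300.0, 420.0])
        assert cov(c * x) == pytest.approx(cov(x), rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cov([-1.0, 1.0])


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        x = [250.0, 260.0, 280.0, 300.0]
        res = permutation_test_cov(x, x, n_resamples=500, seed=0)
        assert res.p_value == 1.0

    def test_p_value_bounds(self):
        rng = np.random.default_rng(3)
        res = permutation_test_cov(
            rng.normal(300, 10, 30), rng.normal(300, 120, 30) + 200,
            n_resamples=999, seed=0,
        )
        assert 1 / 1000 <= res.p_value <= 1.0

    def test_power_against_mixture_alternative(self):
        """The 25 vs 28 °C contrast: a robust-only group against a group with a
        large low-output subpopulation is detected at alpha = 0.01."""
        n_reject = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.normal(300, 30, 400)
            is_low = rng.random(400) < 0.4
            b = np.where(is_low, rng.normal(60, 30, 400), rng.normal(300, 30, 400))
            res = permutation_test_cov(a, b, n_resamples=2000, seed=seed)
            n_reject += res.p_value < 0.01
        assert n_reject >= 0.9 * n_rep


class TestMixtureFit:
    def test_two_component_never_below_single_normal(self):
        """Nesting: the normal+normal family contains the single normal."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(250, 40, 150)
            mix = fit_brood_mixture(x, seed=seed, n_restarts=3, n_boot=0)
            assert mix.loglik >= mix.loglik_single - 1e-6

    def test_well_separated_mixture_recovered(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(250, 30, 350), rng.normal(60, 30, 150)])
        mix = fit_brood_mixture(x, seed=0, n_boot=0)
        assert mix.preferred == "two_component"
        assert mix.weights[0] == pytest.approx(0.7, abs=0.05)
        assert mix.components[0]["mean"] == pytest.approx(250, abs=15)
        assert mix.components[1]["mean"] == pytest.approx(60, abs=15)

    def test_normal_exponential_family(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(250, 30, 300), rng.exponential(50, 120)])
        mix = fit_brood_mixture(x, family="normal+exponential", seed=0, n_boot=0)
        assert mix.preferred == "two_component"
        assert mix.components[1]["dist"] == "exponential"
        assert mix.components[1]["scale"] == pytest.approx(50, rel=0.5)

    def test_matches_reference_em_implementation(self):
        """Cross-check the common-variance normal+normal EM against
        scikit-learn's tied-covariance Gaussian mixture."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(260, 35, 300), rng.normal(80, 25, 200)])
        mix = fit_brood_mixture(x, seed=0, n_boot=0)
        gm = sklearn.GaussianMixture(2, covariance_type="tied", n_init=5,
                                     random_state=0, tol=1e-8).fit(x[:, None])
        ll_sklearn = gm.score(x[:, None]) * len(x)
        assert mix.loglik == pytest.approx(ll_sklearn, abs=0.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_brood_mixture(np.ones(30) * 100, family="cauchy+cauchy")

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_brood_mixture(np.arange(10.0))
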