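"""Unit tests for the one-compartment PK engine."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from smcpk import (
    ConcentrationObservation,
    CovariateLaw,
    CovariateVector,
    DosingRegimen,
    PopPKModel,
    RandomEffects,
    individual_parameters,
    log_likelihood,
    map_estimate,
    map_estimate_batch,
    predict_auc,
    predict_concentration,
    sample_individual,
)
from smcpk.pk import auc_window, concentration_profile


class TestIndividualParameters:
    def test_zero_eta_returns_typical_values(self, simple_model, reference_patient):
        cl, v = individual_parameters(simple_model, reference_patient, RandomEffects.zero())
        assert cl == pytest.approx(5.0)
        assert v == pytest.approx(50.0)

    def test_crcl_power_law_with_eta(self, simple_model):
        # CL = 5 * (50/100)^0.75 * exp(ln 2), evaluated independently
        x = CovariateVector(age=50, height=170, weight=70, crcl=50)
        cl, _ = individual_parameters(simple_model, x, RandomEffects([np.log(2.0), 0.0]))
        assert cl == pytest.approx(5.0 * 0.5**0.75 * 2.0, rel=1e-12)

    def test_nonfinite_covariate_rejected_with_name(self):
        with pytest.raises(ValueError, match="crcl"):
            CovariateVector(age=50, height=170, weight=70, crcl=float("nan"))

    def test_results_strictly_positive(self, simple_model, rng):
        for _ in range(20):
            x = CovariateVector(*rng.uniform([20, 150, 40, 20], [90, 200, 150, 180]))
            eta = RandomEffects(rng.normal(0, 0.5, 2))
            cl, v = individual_parameters(simple_model, x, eta)
            assert cl > 0 and v > 0


class TestPredictConcentration:
    def test_limit_at_time_zero(self, simple_model, reference_patient, regimen):
        c = predict_concentration(
            simple_model, reference_patient, RandomEffects.zero(), regimen, 0.0
        )
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_bolus_limit_closed_form(self, simple_model, reference_patient):
        # infusion_duration -> 0: C(t) = (D/V) exp(-(CL/V) t)
        reg = DosingRegimen(dose=800.0, infusion_duration=1e-6, interval=24.0, n_doses=1)
        cl, v = 5.0, 50.0
        t = 7.3
        c = predict_concentration(simple_model, reference_patient, RandomEffects.zero(), reg, t)
        assert c == pytest.approx(800.0 / v * np.exp(-cl / v * t), rel=1e-5)

    def test_superposition_matches_ode_integration(self, regimen):
        # independent oracle: integrate dA/dt = rate_in(t) - (CL/V) A
        cl, v = 4.0, 60.0
        rate = regimen.dose / regimen.infusion_duration

        def rhs(t, y):
            infusing = any(
                t0 <= t < t0 + regimen.infusion_duration for t0 in regimen.dose_times
            )
            return [(rate if infusing else 0.0) - cl / v * y[0]]

        t_eval = np.linspace(0.0, 47.0, 25)
        sol = solve_ivp(
            rhs, (0, 47.0), [0.0], t_eval=t_eval, rtol=1e-10, atol=1e-12, max_step=0.25
        )
        ours = concentration_profile(cl, v, regimen, t_eval)
        np.testing.assert_allclose(ours, sol.y[0] / v, rtol=1e-5, atol=1e-8)

    def test_time_beyond_horizon_rejected(self, simple_model, reference_patient, regimen):
        with pytest.raises(ValueError, match="horizon"):
            predict_concentration(
                simple_model, reference_patient, RandomEffects.zero(), regimen, 49.0
            )


class TestPredictAuc:
    def test_total_auc_equals_dose_over_clearance(self, simple_model):
        # fast elimination: AUC over [0, 48] captures essentially all exposure
        x = CovariateVector(age=50, height=170, weight=70, crcl=100)
        reg = DosingRegimen(dose=500.0, infusion_duration=0.5, interval=48.0, n_doses=1)
        law = CovariateLaw(cl_typical=5.0, v_typical=10.0)
        model = PopPKModel("fast", law)
        auc = predict_auc(model, x, RandomEffects.zero(), reg, window=(0.0, 48.0))
        assert auc == pytest.approx(500.0 / 5.0, rel=1e-6)

    def test_zero_width_window(self, simple_model, reference_patient, regimen):
        auc = predict_auc(
            simple_model, reference_patient, RandomEffects.zero(), regimen, window=(24.0, 24.0)
        )
        assert auc == 0.0

    def test_linearity_in_dose(self, simple_model, reference_patient):
        aucs = []
        for dose in (500.0, 1000.0):
            reg = DosingRegimen(dose=dose, infusion_duration=1.0, interval=12.0, n_doses=4)
            aucs.append(
                predict_auc(simple_model, reference_patient, RandomEffects.zero(), reg)
            )
        assert aucs[1] == pytest.approx(2.0 * aucs[0], rel=1e-8)

    def test_inverted_window_rejected(self, simple_model, reference_patient, regimen):
        with pytest.raises(ValueError, match="inverted"):
            predict_auc(
                simple_model, reference_patient, RandomEffects.zero(), regimen, window=(30, 20)
            )

    def test_closed_form_matches_quadrature(self, rng):
        # 50 random parameter/regimen draws, adaptive quadrature oracle
        for _ in range(50):
            cl = rng.uniform(1.5, 8.0)
            v = rng.uniform(25.0, 110.0)
            interval = rng.choice([8.0, 12.0, 24.0])
            reg = DosingRegimen(
                dose=rng.uniform(400, 1600),
                infusion_duration=rng.uniform(0.5, 2.0),
                interval=interval,
                n_doses=int(48 // interval),
            )
            lo, hi = sorted(rng.uniform(0.0, 48.0, size=2))
            closed = auc_window(cl, v, reg, lo, hi)
            breaks = np.concatenate(
                [reg.dose_times, reg.dose_times + reg.infusion_duration]
            )
            breaks = [b for b in breaks if lo < b < hi]
            num, _err = quad(
                lambda t: float(concentration_profile(cl, v, reg, t)),
                lo,
                hi,
                points=breaks,
                limit=200,
            )
            assert closed == pytest.approx(num, rel=1e-4, abs=1e-10)


class TestSampleIndividual:
    def test_zero_omega_gives_zero_eta(self, reference_patient, rng):
        law = CovariateLaw(cl_typical=5.0, v_typical=50.0)
        model = PopPKModel("fixed", law, omega_cl=0.0, omega_v=0.0)
        eta = sample_individual(model, reference_patient, rng)
        np.testing.assert_array_equal(eta.eta, 0.0)

    def test_sample_mean_near_zero(self, simple_model, reference_patient):
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_individual(simple_model, reference_patient, rng).eta for _ in range(10_000)]
        )
        se = simple_model.omega / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se)

    def test_identical_seeds_identical_draws(self, simple_model, reference_patient):
        a = sample_individual(simple_model, reference_patient, np.random.default_rng(3)).eta
        b = sample_individual(simple_model, reference_patient, np.random.default_rng(3)).eta
        np.testing.assert_array_equal(a, b)


class TestLogLikelihood:
    def test_empty_observations(self, simple_model, reference_patient, regimen):
        assert log_likelihood(
            simple_model, reference_patient, [], regimen, RandomEffects.zero()
        ) == 0.0

    def test_single_gaussian_closed_form(self, reference_patient, regimen):
        law = CovariateLaw(cl_typical=5.0, v_typical=50.0)
        model = PopPKModel("add_only", law, sigma_prop=0.0, sigma_add=1.3)
        pred = predict_concentration(
            model, reference_patient, RandomEffects.zero(), regimen, 11.5
        )
        obs = [ConcentrationObservation(11.5, pred)]
        ll = log_likelihood(model, reference_patient, obs, regimen, RandomEffects.zero())
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 1.3**2), rel=1e-12)

    def test_monotone_decrease_away_from_prediction(
        self, simple_model, reference_patient, regimen
    ):
        pred = predict_concentration(
            simple_model, reference_patient, RandomEffects.zero(), regimen, 11.5
        )
        lls = [
            log_likelihood(
                simple_model,
                reference_patient,
                [ConcentrationObservation(11.5, pred + delta)],
                regimen,
                RandomEffects.zero(),
            )
            for delta in (0.0, 1.0, 3.0, 8.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestMapEstimate:
    def test_empty_observations_prior_mode(self, simple_model, reference_patient, regimen):
        res = map_estimate(simple_model, reference_patient, [], regimen)
        np.testing.assert_array_equal(res.eta.eta, 0.0)
        assert res.converged

    def test_noise_free_self_inversion(self, reference_patient, regimen):
        law = CovariateLaw(cl_typical=5.0, v_typical=50.0)
        model = PopPKModel("inv", law, omega_cl=0.3, omega_v=0.3, sigma_prop=0.0, sigma_add=0.05)
        eta_star = RandomEffects([0.25, -0.15])
        times = [3.0, 11.5, 23.5]
        obs = [
            ConcentrationObservation(
                t, predict_concentration(model, reference_patient, eta_star, regimen, t)
            )
            for t in times
        ]
        res = map_estimate(model, reference_patient, obs, regimen)
        assert np.max(np.abs(res.eta.eta - eta_star.eta)) < 1e-2

    def test_zero_omega_pins_eta(self, reference_patient, regimen):
        law = CovariateLaw(cl_typical=5.0, v_typical=50.0)
        model = PopPKModel("pinned", law, omega_cl=0.0, omega_v=0.0)
        obs = [ConcentrationObservation(11.5, 30.0)]
        res = map_estimate(model, reference_patient, obs, regimen)
        np.testing.assert_array_equal(res.eta.eta, 0.0)

    def test_batch_agrees_with_scalar_map(self, regimen, rng):
        law = CovariateLaw(cl_typical=4.0, v_typical=55.0, cl_crcl_exp=0.75)
        model = PopPKModel("batch", law, sigma_prop=0.1, sigma_add=0.8)
        n = 8
        X = rng.uniform([30, 155, 50, 40], [80, 190, 120, 160], size=(n, 4))
        times = np.tile([11.5, 23.5, 35.5], (n, 1))
        conc = np.empty_like(times)
        for i in range(n):
            x = CovariateVector.from_array(X[i])
            eta = sample_individual(model, x, rng)
            conc[i] = [
                max(
                    predict_concentration(model, x, eta, regimen, t)
                    + rng.normal(0, 0.5),
                    0.01,
                )
                for t in times[i]
            ]
        eta_b, conv, _ll = map_estimate_batch(model, X, times, conc, regimen)
        for i in range(n):
            obs = [
                ConcentrationObservation(t, c) for t, c in zip(times[i], conc[i])
            ]
            res = map_estimate(model, CovariateVector.from_array(X[i]), obs, regimen)
            np.testing.assert_allclose(eta_b[i], res.eta.eta, atol=2e-4)
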