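"""Weighting methods: SMC, PBMA, naive, combination, confidence."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from smcpk import (
    ConcentrationObservation,
    CovariateLaw,
    CovariateVector,
    EnsembleWeights,
    GaussianLatentDensity,
    ModelEvidence,
    PopPKModel,
    combine_weights,
    confidence_score,
    confidence_threshold,
    ensemble_predict,
    fit_gaussian_support,
    fit_latent_densities,
    model_evidence,
    naive_weights,
    passthrough_encoder,
    pbma_weights,
    pooled_standardizer,
    predict_concentration,
    smc_weights,
    smc_weights_from_logdens,
    RandomEffects,
)
from smcpk.ensemble import evidence_score_from_loglik, pbma_weights_from_scores
from smcpk.zoo import DemographicSummary


def _summaries():
    base = {"age": (50, 10), "height": (170, 8)}
    demos = [
        {**base, "weight": (60, 8), "crcl": (60, 12)},
        {**base, "weight": (85, 8), "crcl": (95, 12)},
        {**base, "weight": (115, 8), "crcl": (130, 12)},
    ]
    return [
        DemographicSummary(
            f"m{i}",
            mean={k: v[0] for k, v in d.items()},
            sd={k: v[1] for k, v in d.items()},
        )
        for i, d in enumerate(demos)
    ]


def _gaussian_latents(summaries, std):
    """Exact latent densities for Gaussian supports under passthrough."""
    out = []
    for s in summaries:
        out.append(
            GaussianLatentDensity(
                s.model_id,
                mean=std.transform(s.mean_array()),
                sd=s.sd_array() / std.scale,
            )
        )
    return out


class TestSmcWeights:
    def test_equal_densities_give_uniform(self):
        logdens = np.full((1, 4), np.log(0.3))
        for mode in ("relative", "absolute"):
            w = smc_weights_from_logdens(logdens, gamma=1e-6, gamma_mode=mode)[0]
            np.testing.assert_allclose(w, 0.25, rtol=1e-12)

    def test_all_zero_densities_give_exact_uniform(self):
        logdens = np.full((1, 3), -np.inf)
        for mode in ("relative", "absolute"):
            w = smc_weights_from_logdens(logdens, gamma=1e-6, gamma_mode=mode)[0]
            np.testing.assert_array_equal(w, 1.0 / 3.0)

    def test_literal_formula_oracle(self):
        # densities (0.8, 0.2, ~0), absolute gamma: (p_i + g) / (sum + 3g)
        g = 1e-6
        dens = np.array([0.8, 0.2, 1e-300])
        with np.errstate(divide="ignore"):
            logdens = np.log(dens)
        w = smc_weights_from_logdens(logdens[None, :], gamma=g, gamma_mode="absolute")[0]
        expected = (dens + g) / (dens.sum() + 3 * g)
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError, match="gamma"):
            smc_weights_from_logdens(np.zeros((1, 2)), gamma=0.0)

    def test_large_gamma_tends_to_uniform(self):
        logdens = np.log(np.array([[0.9, 0.05, 0.05]]))
        w = smc_weights_from_logdens(logdens, gamma=1e9)[0]
        np.testing.assert_allclose(w, 1.0 / 3.0, atol=1e-6)

    def test_dominant_weight_monotone_in_gamma(self):
        logdens = np.log(np.array([[0.9, 0.05, 0.05]]))
        gammas = np.logspace(-8, 2, 15)
        w0 = [smc_weights_from_logdens(logdens, g)[0][0] for g in gammas]
        assert all(a >= b - 1e-12 for a, b in zip(w0, w0[1:]))
        assert w0[0] == pytest.approx(0.9, abs=1e-6)

    def test_passthrough_matches_covariate_space_density_ratio(self, rng):
        # independent oracle: per-covariate normal pdfs multiplied directly
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        encoder = passthrough_encoder(std)
        latents = _gaussian_latents(summaries, std)
        gamma = 1e-6
        for _ in range(100):
            x = rng.uniform([25, 150, 45, 30], [85, 195, 140, 170])
            w = smc_weights(latents, encoder, x, gamma=gamma).weights
            dens = np.array(
                [
                    np.prod(norm.pdf(x, loc=s.mean_array(), scale=s.sd_array()))
                    for s in summaries
                ]
            )
            rel = dens / dens.max()
            expected = (rel + gamma) / (rel + gamma).sum()
            assert np.max(np.abs(w - expected)) < 1e-10

    def test_posterior_recovery_on_hierarchical_draws(self, rng):
        # model index uniform, covariates from that model's Gaussian support:
        # SMC weights = analytic posterior P(model | x) up to gamma
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        encoder = passthrough_encoder(std)
        latents = _gaussian_latents(summaries, std)
        gamma = 1e-6
        N = len(summaries)
        max_err = 0.0
        for _ in range(1000):
            j = rng.integers(N)
            s = summaries[j]
            x = rng.normal(s.mean_array(), s.sd_array())
            x = np.maximum(x, 1.0)
            w = smc_weights(latents, encoder, x, gamma=gamma).weights
            dens = np.array(
                [
                    np.prod(norm.pdf(x, loc=t.mean_array(), scale=t.sd_array()))
                    for t in summaries
                ]
            )
            posterior = dens / dens.sum()
            max_err = max(max_err, np.max(np.abs(w - posterior)))
        assert max_err < 5 * gamma * N


class TestLatentDensities:
    def test_passthrough_gaussian_support_mean_recovered(self, rng):
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        supports = [fit_gaussian_support(s, standardizer=std) for s in summaries]
        encoder = passthrough_encoder(std)
        lds = fit_latent_densities(encoder, supports, n_samples=10_000, rng=rng)
        for ld, s in zip(lds, summaries):
            target = std.transform(s.mean_array())
            sd_z = s.sd_array() / std.scale
            se = sd_z / np.sqrt(ld.n_samples)
            assert np.all(np.abs(ld.kde.samples.mean(axis=0) - target) < 4 * se)

    def test_identical_supports_give_matching_densities(self, rng):
        summaries = _summaries()[:1] * 2
        std = pooled_standardizer(summaries)
        supports = [fit_gaussian_support(s, standardizer=std) for s in summaries]
        encoder = passthrough_encoder(std)
        lds = fit_latent_densities(encoder, supports, n_samples=10_000, rng=rng)
        queries = rng.normal(std.transform(summaries[0].mean_array()), 0.5, size=(10, 4))
        d0 = lds[0].logpdf(queries)
        d1 = lds[1].logpdf(queries)
        assert np.max(np.abs(d0 - d1)) < 0.1

    def test_seeded_determinism(self):
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        supports = [fit_gaussian_support(s, standardizer=std) for s in summaries]
        encoder = passthrough_encoder(std)
        a = fit_latent_densities(encoder, supports, 500, np.random.default_rng(4))
        b = fit_latent_densities(encoder, supports, 500, np.random.default_rng(4))
        np.testing.assert_array_equal(a[0].kde.samples, b[0].kde.samples)

    def test_small_sample_warning_and_error(self):
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        supports = [fit_gaussian_support(s, standardizer=std) for s in summaries]
        encoder = passthrough_encoder(std)
        with pytest.warns(UserWarning, match="small"):
            fit_latent_densities(encoder, supports, 50, np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least 10"):
            fit_latent_densities(encoder, supports, 5, np.random.default_rng(0))


class TestModelEvidence:
    def _two_models(self):
        law_a = CovariateLaw(cl_typical=4.0, v_typical=55.0)
        law_b = CovariateLaw(cl_typical=8.0, v_typical=30.0)
        a = PopPKModel("a", law_a, sigma_prop=0.0, sigma_add=1.0)
        b = PopPKModel("b", law_b, sigma_prop=0.0, sigma_add=1.0)
        return a, b

    def test_bic_closed_form_arithmetic(self):
        assert evidence_score_from_loglik(-1.5, k=2, n_obs=3, score_type="bic") == (
            pytest.approx(2 * np.log(3) + 3.0)
        )

    def test_identical_models_identical_scores(self, reference_patient, regimen):
        a, _ = self._two_models()
        obs = [ConcentrationObservation(11.5, 20.0)]
        ev = model_evidence([a, a], reference_patient, obs, regimen)
        assert ev.scores[0] == ev.scores[1]

    @pytest.mark.parametrize("score_type", ["bic", "aic", "loglik", "neg_sse"])
    def test_observation_on_model_a_favors_a(self, reference_patient, regimen, score_type):
        a, b = self._two_models()
        pred_a = predict_concentration(a, reference_patient, RandomEffects.zero(), regimen, 11.5)
        obs = [ConcentrationObservation(11.5, pred_a)]
        ev = model_evidence([a, b], reference_patient, obs, regimen, score_type)
        assert ev.scores[0] < ev.scores[1]

    def test_empty_observations_uninformative_uniform(self, reference_patient, regimen):
        a, b = self._two_models()
        ev = model_evidence([a, b], reference_patient, [], regimen)
        assert ev.uninformative
        np.testing.assert_array_equal(
            pbma_weights(ev).weights, naive_weights(2).weights
        )


class TestPbmaWeights:
    def test_equal_bics_uniform(self):
        ev = ModelEvidence(scores=np.array([5.0, 5.0, 5.0]), score_type="bic", n_obs=2)
        np.testing.assert_allclose(pbma_weights(ev).weights, 1 / 3, rtol=1e-12)

    def test_closed_form_two_model_case(self):
        # BICs (0, 2 ln 2): exp(0)/(exp(0)+exp(-ln 2)) = 2/3
        ev = ModelEvidence(scores=np.array([0.0, 2 * np.log(2)]), score_type="bic", n_obs=1)
        np.testing.assert_allclose(pbma_weights(ev).weights, [2 / 3, 1 / 3], atol=1e-12)

    def test_softmax_stability_with_large_scores(self):
        w = pbma_weights_from_scores(np.array([[1e4, 1e4 + 2 * np.log(2)]]))[0]
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)


class TestNaiveWeights:
    @pytest.mark.parametrize("n,expected", [(6, 1 / 6), (1, 1.0), (3, 1 / 3)])
    def test_uniform(self, n, expected):
        w = naive_weights(n)
        np.testing.assert_allclose(w.weights, expected, rtol=1e-12)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestCombineWeights:
    def test_uniform_pbma_returns_smc(self):
        w_smc = EnsembleWeights(np.array([0.7, 0.2, 0.1]), "smc")
        w_pbma = naive_weights(3)
        np.testing.assert_allclose(
            combine_weights(w_smc, w_pbma).weights, w_smc.weights, rtol=1e-12
        )

    def test_uniform_smc_returns_pbma(self):
        w_smc = naive_weights(3)
        w_pbma = EnsembleWeights(np.array([0.5, 0.3, 0.2]), "pbma")
        np.testing.assert_allclose(
            combine_weights(w_smc, w_pbma).weights, w_pbma.weights, rtol=1e-12
        )

    def test_product_renormalize_worked_example(self):
        w_smc = EnsembleWeights(np.array([0.5, 0.5, 0.0]), "smc")
        w_pbma = EnsembleWeights(np.array([0.2, 0.6, 0.2]), "pbma")
        np.testing.assert_allclose(
            combine_weights(w_smc, w_pbma).weights, [0.25, 0.75, 0.0], atol=1e-12
        )

    def test_zero_product_falls_back_to_smc(self, caplog):
        w_smc = EnsembleWeights(np.array([1.0, 0.0]), "smc")
        w_pbma = EnsembleWeights(np.array([0.0, 1.0]), "pbma")
        with caplog.at_level("WARNING"):
            out = combine_weights(w_smc, w_pbma)
        np.testing.assert_array_equal(out.weights, w_smc.weights)
        assert any("zero" in r.message for r in caplog.records)


class TestEnsemblePredict:
    def test_constant_predictions(self):
        w = EnsembleWeights(np.array([0.3, 0.7]), "naive")
        assert ensemble_predict(np.array([420.0, 420.0]), w) == pytest.approx(420.0)

    def test_one_hot_selection_ignores_other_models(self):
        w = EnsembleWeights(np.array([0.0, 1.0, 0.0]), "smc")
        assert ensemble_predict(np.array([np.nan, 333.0, np.nan]), w) == 333.0

    def test_weighted_mean_arithmetic(self):
        w = EnsembleWeights(np.array([0.25, 0.75]), "smc")
        assert ensemble_predict(np.array([300.0, 500.0]), w) == pytest.approx(450.0)

    def test_nan_with_nonzero_weight_rejected(self):
        w = EnsembleWeights(np.array([0.5, 0.5]), "naive")
        with pytest.raises(ValueError, match="non-finite"):
            ensemble_predict(np.array([np.nan, 400.0]), w)


class TestConfidence:
    def _setup(self):
        summaries = _summaries()
        std = pooled_standardizer(summaries)
        return summaries, std, passthrough_encoder(std), _gaussian_latents(summaries, std)

    def test_centroid_scores_above_far_outlier(self):
        summaries, std, enc, latents = self._setup()
        center = summaries[1].mean_array()
        outlier = center + 10 * std.scale * np.array([1, 1, 1, 1])
        c_in = confidence_score(latents, enc, center)
        c_out = confidence_score(latents, enc, outlier)
        assert c_in.total_density > c_out.total_density

    def test_outlier_flagged_under_cohort_threshold(self, rng):
        summaries, std, enc, latents = self._setup()
        cohort = np.vstack(
            [rng.normal(s.mean_array(), s.sd_array(), size=(200, 4)) for s in summaries]
        )
        thresh = confidence_threshold(latents, enc, cohort, quantile=0.01)
        outlier = summaries[1].mean_array() + 10 * std.scale
        assert confidence_score(latents, enc, outlier, thresh).low_confidence
        assert not confidence_score(
            latents, enc, summaries[1].mean_array(), thresh
        ).low_confidence

    def test_invariant_to_model_order(self):
        summaries, std, enc, latents = self._setup()
        x = summaries[0].mean_array() + 5.0
        a = confidence_score(latents, enc, x).total_density
        b = confidence_score(latents[::-1], enc, x).total_density
        assert a == pytest.approx(b, rel=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    logdens=st.lists(
        st.floats(min_value=-300, max_value=10), min_size=2, max_size=8
    ),
    gamma=st.floats(min_value=1e-12, max_value=1e3),
)
def test_smc_weights_always_on_simplex(logdens, gamma):
    w = smc_weights_from_logdens(np.array([logdens]), gamma=gamma)[0]
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-12


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    scores=st.lists(
        st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=8
    )
)
def test_pbma_weights_always_on_simplex(scores):
    w = pbma_weights_from_scores(np.array([scores]))[0]
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-12
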