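"""Relative-error metrics and the full method-comparison experiment.

Predictions are scored against the simulated true AUC by relative bias
(mean percent error, signed in machine output) and relative RMSE (root mean
squared percent error), with nonparametric patient-level bootstrap standard
errors. ``run_experiment`` runs every method — each model alone, the naive
ensemble, PBMA, SMC, and SMC x PBMA — across observation counts 0-3 on a
simulated cohort, end-to-end seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .density import SupportDensity, fit_gaussian_support, pooled_standardizer
from .ensemble import (
    fit_latent_densities,
    confidence_threshold,
    evidence_score_from_loglik,
    pbma_weights_from_scores,
    smc_weights_from_logdens,
)
from .pk import (
    DEFAULT_AUC_WINDOW,
    DEFAULT_REGIMEN,
    DosingRegimen,
    PopPKModel,
    _residual_variance,
    auc_window,
    concentration_profile,
    map_estimate_batch,
)
from .representation import EncoderConfig, PassthroughEncoder, fit_encoder
from .zoo import DemographicSummary

__all__ = [
    "rbias",
    "rrmse",
    "bootstrap_se",
    "run_experiment",
    "ExperimentResult",
    "ENSEMBLE_METHODS",
]

ENSEMBLE_METHODS = ("naive", "pbma", "smc", "smc_pbma")


def _relative_errors(pred, truth) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if np.any(truth <= 0):
        raise ValueError("truth values must be strictly positive")
    return (pred - truth) / truth


def rbias(pred, truth) -> float:
    """Mean relative error in percent (signed)."""
    return float(100.0 * np.mean(_relative_errors(pred, truth)))


def rrmse(pred, truth) -> float:
    """Root-mean-square relative error in percent."""
    return float(100.0 * np.sqrt(np.mean(_relative_errors(pred, truth) ** 2)))


def bootstrap_se(
    metric, pred, truth, B: int = 200, rng: np.random.Generator | None = None
) -> float:
    """SD of `metric` (rbias/rrmse or a callable) over B patient resamples."""
    if B < 100:
        raise ValueError("B must be at least 100")
    fn = {"rbias": rbias, "rrmse": rrmse}.get(metric, metric)
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    rng = rng or np.random.default_rng()
    n = len(pred)
    idx = rng.integers(n, size=(B, n))
    vals = np.array([fn(pred[i], truth[i]) for i in idx])
    return float(vals.std(ddof=1))


def _boot_stats(err: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    """(se_rbias, se_rrmse) from shared bootstrap index matrix."""
    res = err[idx]
    biases = 100.0 * res.mean(axis=1)
    rmses = 100.0 * np.sqrt((res**2).mean(axis=1))
    return float(biases.std(ddof=1)), float(rmses.std(ddof=1))


@dataclass
class ExperimentResult:
    """Method-comparison outputs: the results table plus per-patient artifacts."""

    results: pd.DataFrame
    predictions: pd.DataFrame
    cohort: list
    run_log: dict
    weights: pd.DataFrame | None = None
    supports: list[SupportDensity] = field(default_factory=list)
    encoder: object = None
    latent_densities: list = field(default_factory=list)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"experiment stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_experiment(
    zoo: list[tuple[PopPKModel, DemographicSummary]],
    *,
    generating_zoo: list[tuple[PopPKModel, DemographicSummary]] | None = None,
    regime: str = "realistic",
    n_total: int = 1000,
    n_per_model: int | None = None,
    regimen: DosingRegimen = DEFAULT_REGIMEN,
    n_obs_levels: tuple[int, ...] = (0, 1, 2, 3),
    encoder_config: EncoderConfig | None = None,
    gamma: float = 1e-6,
    gamma_mode: str = "relative",
    score_type: str = "bic",
    n_latent_samples: int = 2000,
    bootstrap_B: int = 200,
    auc_win: tuple[float, float] = DEFAULT_AUC_WINDOW,
    seed: int = 0,
) -> ExperimentResult:
    """Run the full ensembling comparison on a simulated cohort.

    Parameters
    ----------
    zoo : (model, demographic summary) pairs forming the ensemble.
    generating_zoo : pairs that generate patients (defaults to `zoo`);
        letting them differ exercises the case of a model in the ensemble
        that never generated data.
    regime : "original" (equal share per model), "realistic"
        (density-proportional generator choice) or "rejection"
        (original cohort filtered by argmax support likelihood).
    n_total / n_per_model : cohort sizing; n_per_model applies to the
        original and rejection regimes (default n_total // n_models).
    encoder_config : None uses the passthrough (standardize-only) encoder;
        an :class:`EncoderConfig` trains the representation network.

    A priori (0-observation) per-model predictions use population-typical
    eta = 0; with observations each model's prediction uses its own MAP
    eta, and the PBMA evidence reuses that same fit.
    """
    generating_zoo = generating_zoo or zoo
    models = [m for m, _ in zoo]
    summaries = [s for _, s in zoo]
    gen_models = [m for m, _ in generating_zoo]
    gen_summaries = [s for _, s in generating_zoo]
    n_models = len(models)
    run_log: dict = {"seed": seed, "regime": regime, "n_models": n_models}

    ss = np.random.SeedSequence(seed)
    seed_cohort, seed_obs, seed_latent, seed_enc, seed_boot = ss.spawn(5)
    rng_cohort = np.random.default_rng(seed_cohort)
    rng_obs = np.random.default_rng(seed_obs)
    rng_latent = np.random.default_rng(seed_latent)
    rng_boot = np.random.default_rng(seed_boot)

    with _stage("fit-supports"):
        all_summaries = {s.model_id: s for s in summaries + gen_summaries}
        standardizer = pooled_standardizer(list(all_summaries.values()))
        supports = [fit_gaussian_support(s, standardizer=standardizer) for s in summaries]
        gen_supports = [
            fit_gaussian_support(s, standardizer=standardizer) for s in gen_summaries
        ]

    with _stage("simulate-cohort"):
        spec = cohort_mod.global_spec_from_summaries(gen_summaries)
        if regime == "original":
            npm = n_per_model or max(n_total // len(gen_models), 1)
            patients = cohort_mod.simulate_original_cohort(
                gen_models, spec, npm, regimen, rng_cohort, auc_win
            )
        elif regime == "realistic":
            patients, log = cohort_mod.simulate_realistic_cohort(
                gen_models, gen_supports, spec, n_total, regimen, rng_cohort, auc_win
            )
            run_log["cohort"] = log
        elif regime == "rejection":
            npm = n_per_model or max(n_total // len(gen_models), 1)
            base = cohort_mod.simulate_original_cohort(
                gen_models, spec, npm, regimen, rng_cohort, auc_win
            )
            patients, log = cohort_mod.rejection_subsample(base, gen_supports)
            run_log["cohort"] = log
        else:
            raise ValueError(f"unknown cohort regime {regime!r}")
        if not patients:
            raise ValueError("cohort simulation produced no patients")
        n = len(patients)
        run_log["n_patients"] = n
        X = np.stack([p.covariates.as_array() for p in patients])
        truth = np.array([p.auc_true for p in patients])

    with _stage("fit-encoder"):
        if encoder_config is None:
            encoder = PassthroughEncoder(standardizer)
        else:
            train_draws = {
                s.model_id: s.sample(max(n_latent_samples // 2, 200), rng_latent)
                for s in supports
            }
            encoder = fit_encoder(X, train_draws, encoder_config)

    with _stage("fit-latent"):
        latent_densities = fit_latent_densities(
            encoder, supports, n_latent_samples, rng_latent
        )
        Z = encoder.encode(X)
        logdens = np.stack([np.atleast_1d(ld.logpdf(Z)) for ld in latent_densities], axis=1)
        if n_models >= 2:
            W_smc = smc_weights_from_logdens(logdens, gamma, gamma_mode)
        else:
            W_smc = np.ones((n, 1))
        conf = np.sum(np.where(np.isfinite(logdens), np.exp(logdens), 0.0), axis=1)
        conf_thresh = confidence_threshold(latent_densities, encoder, X)
        low_conf = conf < conf_thresh

    with _stage("sample-observations"):
        max_level = max(n_obs_levels)
        gen_by_id = {m.model_id: m for m in gen_models}
        times_design = np.asarray(cohort_mod.DEFAULT_OBS_TIMES[:max_level], dtype=float)
        times = np.tile(times_design, (n, 1)) if max_level else np.zeros((n, 0))
        conc = np.zeros((n, max_level))
        observed_patients = []
        for i, p in enumerate(patients):
            pobs = cohort_mod.sample_observations(p, gen_by_id[p.generating_model_id], max_level, rng_obs)
            observed_patients.append(pobs)
            conc[i] = [o.concentration for o in pobs.observations]
        patients = observed_patients

    W_naive = np.full((n, n_models), 1.0 / n_models)
    results_rows = []
    pred_rows = []
    weight_rows = []
    model_ids = [m.model_id for m in models]
    patient_ids = np.array([p.patient_id for p in patients])
    k_per_model = [int(np.sum(m.omega > 0)) for m in models]

    idx_boot = rng_boot.integers(n, size=(bootstrap_B, n))

    for level in n_obs_levels:
        with _stage(f"predict-level-{level}"):
            auc_pred = np.empty((n, n_models))
            scores = np.zeros((n, n_models))
            for j, model in enumerate(models):
                tvcl, tvv = model.law.typical_values(X)
                if level == 0:
                    eta = np.zeros((n, 2))
                else:
                    eta, _conv, ll = map_estimate_batch(
                        model, X, times[:, :level], conc[:, :level], regimen
                    )
                    if score_type == "neg_sse":
                        cl = (tvcl * np.exp(eta[:, 0]))[:, None]
                        v = (tvv * np.exp(eta[:, 1]))[:, None]
                        pred_c = concentration_profile(cl, v, regimen, times[:, :level])
                        var_hat = np.maximum(
                            _residual_variance(model, pred_c).mean(axis=1), 1e-12
                        )
                        scores[:, j] = ((conc[:, :level] - pred_c) ** 2).sum(axis=1) / var_hat
                    else:
                        scores[:, j] = evidence_score_from_loglik(
                            ll, k_per_model[j], level, score_type
                        )
                cl = tvcl * np.exp(eta[:, 0])
                v = tvv * np.exp(eta[:, 1])
                auc_pred[:, j] = auc_window(cl, v, regimen, *auc_win)

            # a priori PBMA has no evidence: exactly the naive weights
            W_pbma = W_naive if level == 0 else pbma_weights_from_scores(scores)
            prod = W_smc * W_pbma
            tot = prod.sum(axis=1, keepdims=True)
            zero_rows = tot[:, 0] <= 0
            tot[zero_rows] = 1.0
            W_comb = prod / tot
            W_comb[zero_rows] = W_smc[zero_rows]

            for method, W in (
                ("naive", W_naive),
                ("pbma", W_pbma),
                ("smc", W_smc),
                ("smc_pbma", W_comb),
            ):
                weight_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": np.repeat(patient_ids, n_models),
                            "method": method,
                            "n_obs_used": level,
                            "model_id": np.tile(model_ids, n),
                            "weight": W.ravel(),
                        }
                    )
                )

            method_preds = {m.model_id: auc_pred[:, j] for j, m in enumerate(models)}
            method_preds["naive"] = (auc_pred * W_naive).sum(axis=1)
            method_preds["pbma"] = (auc_pred * W_pbma).sum(axis=1)
            method_preds["smc"] = (auc_pred * W_smc).sum(axis=1)
            method_preds["smc_pbma"] = (auc_pred * W_comb).sum(axis=1)

            for method, pred in method_preds.items():
                err = _relative_errors(pred, truth)
                se_b, se_r = _boot_stats(err, idx_boot)
                results_rows.append(
                    {
                        "method": method,
                        "n_obs": level,
                        "rbias": 100.0 * err.mean(),
                        "se_rbias": se_b,
                        "rrmse": 100.0 * np.sqrt((err**2).mean()),
                        "se_rrmse": se_r,
                        "n_patients": n,
                    }
                )
                pred_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": [p.patient_id for p in patients],
                            "method": method,
                            "n_obs_used": level,
                            "auc_pred": pred,
                            "auc_true": truth,
                            "confidence": conf,
                            "low_confidence_flag": low_conf,
                        }
                    )
                )

    results = pd.DataFrame(results_rows)
    predictions = pd.concat(pred_rows, ignore_index=True)
    weights = pd.concat(weight_rows, ignore_index=True)
    run_log["confidence_threshold"] = conf_thresh
    run_log["n_low_confidence"] = int(low_conf.sum())
    return ExperimentResult(
        results=results,
        predictions=predictions,
        weights=weights,
        cohort=patients,
        run_log=run_log,
        supports=supports,
        encoder=encoder,
        latent_densities=latent_densities,
    )
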