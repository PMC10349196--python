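"""Synthetic evaluation cohorts in two generative regimes.

``original``: covariates are drawn from one global population and each model
generates an equal share of patients regardless of whether the covariates
resemble its training domain — the setting where density-aware weighting has
little to exploit.

``realistic``: covariates come from the same global population but the
generating model is drawn with probability proportional to the likelihood
that the individual came from each model's population. Its subsampling
counterpart, ``rejection_subsample``, filters an original cohort down to the
patients whose argmax-likelihood model matches their generator.

Sparse concentration observations (0-3 per patient over 48 h) are sampled at
a fixed trough-oriented design with the generating model's residual error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .density import SupportDensity
from .pk import (
    ConcentrationObservation,
    CovariateVector,
    DosingRegimen,
    DEFAULT_AUC_WINDOW,
    DEFAULT_REGIMEN,
    HORIZON_H,
    PopPKModel,
    RandomEffects,
    auc_window,
    concentration_profile,
)
from .zoo import DemographicSummary

__all__ = [
    "GlobalPopulationSpec",
    "SimulatedPatient",
    "sample_global_covariates",
    "simulate_original_cohort",
    "rejection_subsample",
    "simulate_realistic_cohort",
    "sample_observations",
    "DEFAULT_OBS_TIMES",
    "global_spec_from_summaries",
]

#: Trough-oriented fixed sampling times (h) for 1, 2, 3 observations.
DEFAULT_OBS_TIMES = (11.5, 23.5, 35.5)


@dataclass(frozen=True)
class GlobalPopulationSpec:
    """Pooled covariate population: per-covariate Gaussian moments with
    positivity clamp bounds."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sd <= 0):
            raise ValueError("global population SDs must be positive")
        if np.any(self.lower <= 0) or np.any(self.upper <= self.lower):
            raise ValueError("clamp bounds must be positive with upper > lower")


def global_spec_from_summaries(
    summaries: list[DemographicSummary], sd_inflation: float = 1.0
) -> GlobalPopulationSpec:
    """Global population as the pooled mixture of the zoo's demographics."""
    means = np.stack([s.mean_array() for s in summaries])
    sds = np.stack([s.sd_array() for s in summaries])
    mix_mean = means.mean(axis=0)
    mix_sd = np.sqrt((sds**2 + means**2).mean(axis=0) - mix_mean**2) * sd_inflation
    return GlobalPopulationSpec(
        mean=mix_mean,
        sd=mix_sd,
        lower=np.maximum(mix_mean - 6 * mix_sd, np.array([16.0, 120.0, 30.0, 10.0])),
        upper=mix_mean + 6 * mix_sd,
    )


@dataclass(frozen=True)
class SimulatedPatient:
    """One simulated patient with ground truth and sparse observations."""

    patient_id: int
    covariates: CovariateVector
    generating_model_id: str
    eta_true: RandomEffects
    auc_true: float
    regimen: DosingRegimen
    observations: tuple[ConcentrationObservation, ...] = ()

    def __post_init__(self) -> None:
        if self.auc_true <= 0:
            raise ValueError("true AUC must be positive")
        if len(self.observations) > 3:
            raise ValueError("at most 3 observations per patient")
        times = [o.time for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")


def sample_global_covariates(
    spec: GlobalPopulationSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n independent Gaussian covariate rows, clamped to the spec's bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    X = rng.normal(spec.mean, spec.sd, size=(n, len(spec.mean)))
    return np.clip(X, spec.lower, spec.upper)


def _make_patients(models, model_idx, X, regimen, auc_win, rng, id_offset=0):
    """Simulate truth (eta, AUC) for covariate rows with assigned generators."""
    patients = []
    etas = np.empty((len(model_idx), 2))
    for j, model in enumerate(models):
        rows = np.flatnonzero(model_idx == j)
        if rows.size:
            etas[rows] = rng.normal(0.0, model.omega, size=(rows.size, 2))
    for i, (xi, j) in enumerate(zip(X, model_idx)):
        model = models[j]
        tvcl, tvv = model.law.typical_values(xi)
        cl = float(tvcl[0] * np.exp(etas[i, 0]))
        v = float(tvv[0] * np.exp(etas[i, 1]))
        auc = float(auc_window(cl, v, regimen, *auc_win))
        patients.append(
            SimulatedPatient(
                patient_id=id_offset + i,
                covariates=CovariateVector.from_array(xi),
                generating_model_id=model.model_id,
                eta_true=RandomEffects(etas[i]),
                auc_true=auc,
                regimen=regimen,
            )
        )
    return patients


def simulate_original_cohort(
    models: list[PopPKModel],
    spec: GlobalPopulationSpec,
    n_per_model: int,
    regimen: DosingRegimen = DEFAULT_REGIMEN,
    rng: np.random.Generator | None = None,
    auc_win: tuple[float, float] = DEFAULT_AUC_WINDOW,
) -> list[SimulatedPatient]:
    """Global covariates; each model generates exactly n_per_model patients."""
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    rng = rng or np.random.default_rng()
    n_total = n_per_model * len(models)
    X = sample_global_covariates(spec, n_total, rng)
    model_idx = np.repeat(np.arange(len(models)), n_per_model)
    return _make_patients(models, model_idx, X, regimen, auc_win, rng)


def rejection_subsample(
    cohort: list[SimulatedPatient],
    supports: list[SupportDensity],
) -> tuple[list[SimulatedPatient], dict]:
    """Keep patients whose argmax-support-likelihood model matches their
    generator; the subsampling counterpart of the realistic regime.

    Ties at the argmax discard the patient (counted in the returned log).
    Returns (retained patients in original order, log dict).
    """
    id_to_col = {s.model_id: j for j, s in enumerate(supports)}
    for p in cohort:
        if p.generating_model_id not in id_to_col:
            raise ValueError(f"no support density for model '{p.generating_model_id}'")
    X = np.stack([p.covariates.as_array() for p in cohort])
    logdens = np.stack([s.logpdf(X) for s in supports], axis=1)
    best = logdens.max(axis=1)
    is_best = logdens == best[:, None]
    ties = is_best.sum(axis=1) > 1
    argmax = logdens.argmax(axis=1)
    gen_col = np.array([id_to_col[p.generating_model_id] for p in cohort])
    keep = (argmax == gen_col) & ~ties
    retained = [p for p, k in zip(cohort, keep) if k]
    log = {
        "n_input": len(cohort),
        "n_retained": len(retained),
        "n_ties_discarded": int(ties.sum()),
        "retention_fraction": len(retained) / len(cohort) if cohort else 0.0,
    }
    return retained, log


def simulate_realistic_cohort(
    models: list[PopPKModel],
    supports: list[SupportDensity],
    spec: GlobalPopulationSpec,
    n_total: int,
    regimen: DosingRegimen = DEFAULT_REGIMEN,
    rng: np.random.Generator | None = None,
    auc_win: tuple[float, float] = DEFAULT_AUC_WINDOW,
) -> tuple[list[SimulatedPatient], dict]:
    """Global covariates; each patient's generating model drawn with
    probability proportional to its support density at the covariates."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if len(models) != len(supports):
        raise ValueError("one support density per model required")
    rng = rng or np.random.default_rng()
    X = sample_global_covariates(spec, n_total, rng)
    logdens = np.stack([s.logpdf(X) for s in supports], axis=1)
    m = logdens.max(axis=1, keepdims=True)
    p = np.exp(logdens - np.where(np.isfinite(m), m, 0.0))
    p = np.where(np.isfinite(p), p, 0.0)
    row_tot = p.sum(axis=1)
    degenerate = row_tot <= 0
    p[degenerate] = 1.0
    p = p / p.sum(axis=1, keepdims=True)
    u = rng.random(n_total)
    model_idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    patients = _make_patients(models, model_idx, X, regimen, auc_win, rng)
    log = {"n_total": n_total, "n_degenerate_density": int(degenerate.sum())}
    return patients, log


def sample_observations(
    patient: SimulatedPatient,
    model: PopPKModel,
    n_obs: int,
    rng: np.random.Generator,
    design: tuple[float, ...] = DEFAULT_OBS_TIMES,
) -> SimulatedPatient:
    """Attach n_obs noisy concentration measurements at the design times.

    Concentrations are the noise-free prediction at the patient's true eta
    plus combined proportional+additive residual error, clamped at zero.
    """
    if n_obs not in (0, 1, 2, 3):
        raise ValueError("n_obs must be one of {0, 1, 2, 3}")
    if n_obs == 0:
        return replace(patient, observations=())
    times = np.asarray(design[:n_obs], dtype=float)
    if np.any(times > HORIZON_H) or np.any(np.diff(times) <= 0):
        raise ValueError("design times must be strictly increasing within the horizon")
    tvcl, tvv = model.law.typical_values(patient.covariates)
    cl = float(tvcl[0] * np.exp(patient.eta_true.eta[0]))
    v = float(tvv[0] * np.exp(patient.eta_true.eta[1]))
    pred = concentration_profile(cl, v, patient.regimen, times)
    noisy = pred * (1.0 + model.sigma_prop * rng.normal(size=n_obs)) + model.sigma_add * rng.normal(
        size=n_obs
    )
    obs = tuple(
        ConcentrationObservation(time=float(t), concentration=float(max(c, 0.0)))
        for t, c in zip(times, noisy)
    )
    return replace(patient, observations=obs)
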