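"""Ensemble weighting: instance-wise SMC weights, global PBMA/BIC weights,
naive weights, and their combination.

SMC weights a model i at test point x by the density of the encoded
covariates under that model's latent-space support density:

    w_i(x) = (p_i^Z(f_theta(x)) + gamma) / sum_j (p_j^Z(f_theta(x)) + gamma)

with a small regularizer gamma so a far outlier is not handed entirely to
whichever model happens to be nearest: as all densities vanish the weights
tend to 1/N. Densities enter on the natural scale. Because densities carry
units, the default interpretation of gamma is *relative* to the per-query
maximum density (scale-free, preserves the outlier limit exactly); the
literal absolute form is available via ``gamma_mode="absolute"``.

PBMA turns a per-model evidence score (BIC by default) into global weights
via p(M_i | D) = exp(-BIC_i / 2) / sum_j exp(-BIC_j / 2); with no
observations it degenerates to the naive equal-weight ensemble. SMC and
PBMA weights combine as prior x evidence: elementwise product,
renormalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .density import DiagKDE, SupportDensity
from .pk import (
    ConcentrationObservation,
    CovariateVector,
    DosingRegimen,
    PopPKModel,
    log_likelihood,
    map_estimate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LatentDensity",
    "GaussianLatentDensity",
    "EnsembleWeights",
    "ModelEvidence",
    "fit_latent_densities",
    "smc_weights",
    "smc_weights_from_logdens",
    "model_evidence",
    "pbma_weights",
    "pbma_weights_from_scores",
    "naive_weights",
    "combine_weights",
    "ensemble_predict",
    "confidence_score",
    "confidence_threshold",
    "ConfidenceResult",
    "SCORE_TYPES",
]

SCORE_TYPES = ("bic", "aic", "loglik", "neg_sse")

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class EnsembleWeights:
    """Simplex-constrained weight vector over models."""

    weights: np.ndarray
    provenance: str
    gamma: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0):
            raise ValueError("ensemble weights must be non-negative")
        if abs(w.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"ensemble weights must sum to 1 within {_SIMPLEX_TOL}, got {w.sum()!r}")

    @property
    def n_models(self) -> int:
        return len(self.weights)


class LatentDensity:
    """KDE over a model's support samples encoded into latent space (p_j^Z)."""

    def __init__(self, model_id: str, kde: DiagKDE):
        self.model_id = model_id
        self.kde = kde

    @property
    def n_samples(self) -> int:
        return self.kde.n

    def logpdf(self, z) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        out = self.kde.logpdf(np.atleast_2d(z))
        return float(out[0]) if single else out


class GaussianLatentDensity:
    """Exact diagonal-Gaussian latent density.

    Used where the latent distribution is known in closed form (for example
    a Gaussian support passed through a passthrough encoder); interchangeable
    with :class:`LatentDensity` anywhere a latent density is accepted.
    """

    def __init__(self, model_id: str, mean: np.ndarray, sd: np.ndarray):
        self.model_id = model_id
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ValueError("SDs must be strictly positive")

    def logpdf(self, z) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = np.atleast_2d(z)
        u = (Z - self.mean) / self.sd
        out = -0.5 * np.sum(u**2, axis=1) - 0.5 * len(self.sd) * np.log(2 * np.pi) - np.sum(
            np.log(self.sd)
        )
        return float(out[0]) if single else out


def fit_latent_densities(
    encoder,
    supports: list[SupportDensity],
    n_samples: int = 2000,
    rng: np.random.Generator | None = None,
    bandwidth_rule: str = "scott",
) -> list[LatentDensity]:
    """Re-model every support density in latent space.

    For each model: draw ``n_samples`` covariate rows from its support,
    encode them, and fit a KDE in the latent space.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be at least 10")
    if n_samples < 100:
        warnings.warn(
            f"n_samples={n_samples} is small for a latent KDE; densities will be noisy",
            stacklevel=2,
        )
    rng = rng or np.random.default_rng()
    out = []
    for support in supports:
        X = support.sample(n_samples, rng)
        Z = encoder.encode(X)
        out.append(LatentDensity(support.model_id, DiagKDE.from_rule(Z, bandwidth_rule)))
    return out


def _logdens_matrix(latent_densities, Z: np.ndarray) -> np.ndarray:
    return np.stack([np.atleast_1d(ld.logpdf(Z)) for ld in latent_densities], axis=1)


def smc_weights_from_logdens(
    logdens: np.ndarray, gamma: float, gamma_mode: str = "relative"
) -> np.ndarray:
    """SMC weight matrix (n, N) from a log-density matrix (n, N).

    relative mode: densities are rescaled per query so the largest equals 1
    before gamma is added (gamma acts relative to the dominant density);
    absolute mode: the printed formula applied literally on the natural
    scale. Queries where every density underflows to zero get uniform
    weights in both modes (the gamma-dominated limit).
    """
    if gamma <= 0:
        raise ValueError("gamma must be strictly positive")
    if gamma_mode not in ("relative", "absolute"):
        raise ValueError(f"unknown gamma_mode {gamma_mode!r}")
    logdens = np.atleast_2d(np.asarray(logdens, dtype=float))
    n, N = logdens.shape
    if N < 2:
        raise ValueError("need at least 2 models")
    m = logdens.max(axis=1, keepdims=True)
    dead = ~np.isfinite(m[:, 0])
    m = np.where(np.isfinite(m), m, 0.0)
    if gamma_mode == "relative":
        p = np.exp(logdens - m)
    else:
        p = np.exp(logdens)
    p = np.where(np.isfinite(p), p, 0.0)
    num = p + (gamma if gamma_mode == "relative" else gamma)
    if gamma_mode == "absolute":
        underflow = p.sum(axis=1) == 0.0
        dead = dead | underflow
    w = num / num.sum(axis=1, keepdims=True)
    w[dead] = 1.0 / N
    return w


def smc_weights(
    latent_densities: list,
    encoder,
    x,
    gamma: float = 1e-6,
    gamma_mode: str = "relative",
) -> EnsembleWeights:
    """Instance-wise SMC weights for a single test point x."""
    if len(latent_densities) < 2:
        raise ValueError("need at least 2 models")
    z = encoder.encode(x)
    logdens = _logdens_matrix(latent_densities, np.atleast_2d(z))
    w = smc_weights_from_logdens(logdens, gamma, gamma_mode)[0]
    return EnsembleWeights(weights=w, provenance="smc", gamma=gamma)


@dataclass(frozen=True)
class ModelEvidence:
    """Per-model performance scores on a patient's observations."""

    scores: np.ndarray
    score_type: str
    n_obs: int
    uninformative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"unknown score type {self.score_type!r}")
        if not self.uninformative and not np.all(np.isfinite(self.scores)):
            raise ValueError("evidence scores must be finite")


def evidence_score_from_loglik(
    maxloglik: float, k: int, n_obs: int, score_type: str, sse: float | None = None
) -> float:
    """Map a model's maximized log-likelihood to the common deviance scale.

    bic = k ln n - 2 ll; aic = 2k - 2 ll; loglik enters as -2 ll so the
    one softmax formula serves every score type; neg_sse enters as the
    variance-scaled SSE.
    """
    if score_type == "bic":
        return k * np.log(n_obs) - 2.0 * maxloglik
    if score_type == "aic":
        return 2.0 * k - 2.0 * maxloglik
    if score_type == "loglik":
        return -2.0 * maxloglik
    if score_type == "neg_sse":
        if sse is None:
            raise ValueError("neg_sse requires the scaled SSE")
        return sse
    raise ValueError(f"unknown score type {score_type!r}")


def model_evidence(
    models: list[PopPKModel],
    x: CovariateVector,
    obs: list[ConcentrationObservation],
    regimen: DosingRegimen,
    score_type: str = "bic",
) -> ModelEvidence:
    """Per-model evidence from MAP-fitted individual parameters.

    k is the number of individual-level parameters optimized at prediction
    time (the eta dimension): the structural model itself is fixed, only the
    individualization is fitted to the observations.
    """
    if score_type not in SCORE_TYPES:
        raise ValueError(f"unknown score type {score_type!r}")
    if not obs:
        return ModelEvidence(
            scores=np.zeros(len(models)), score_type=score_type, n_obs=0, uninformative=True
        )
    scores = []
    for model in models:
        fit = map_estimate(model, x, obs, regimen)
        ll = log_likelihood(model, x, obs, regimen, fit.eta)
        sse = None
        if score_type == "neg_sse":
            from .pk import _residual_variance, predict_concentration

            times = np.array([o.time for o in obs])
            conc = np.array([o.concentration for o in obs])
            pred = np.asarray(predict_concentration(model, x, fit.eta, regimen, times))
            var_hat = float(np.mean(_residual_variance(model, pred)))
            sse = float(np.sum((conc - pred) ** 2) / max(var_hat, 1e-12))
        k = int(np.sum(model.omega > 0))
        scores.append(evidence_score_from_loglik(ll, k, len(obs), score_type, sse))
    return ModelEvidence(scores=np.array(scores), score_type=score_type, n_obs=len(obs))


def pbma_weights_from_scores(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax of -score/2 with max subtraction (stable)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    half = -0.5 * scores
    half = half - half.max(axis=1, keepdims=True)
    e = np.exp(half)
    return e / e.sum(axis=1, keepdims=True)


def pbma_weights(evidence: ModelEvidence) -> EnsembleWeights:
    """Global performance-based weights p(M_i | D) = softmax(-score_i / 2).

    Uninformative evidence (no observations) yields uniform weights — the
    naive-ensemble degeneracy of performance-based averaging.
    """
    n = len(evidence.scores)
    if evidence.uninformative:
        return EnsembleWeights(weights=np.full(n, 1.0 / n), provenance="pbma")
    return EnsembleWeights(weights=pbma_weights_from_scores(evidence.scores)[0], provenance="pbma")


def naive_weights(n: int) -> EnsembleWeights:
    """Equal weights w = 1/N."""
    if n < 1:
        raise ValueError("need at least 1 model")
    return EnsembleWeights(weights=np.full(n, 1.0 / n), provenance="naive")


def combine_weights(w_smc: EnsembleWeights, w_pbma: EnsembleWeights) -> EnsembleWeights:
    """Prior x evidence combination: elementwise product, renormalized."""
    if w_smc.n_models != w_pbma.n_models:
        raise ValueError("weight vectors must cover the same models")
    prod = w_smc.weights * w_pbma.weights
    total = prod.sum()
    if total <= 0:
        logger.warning("SMC x PBMA product is identically zero; falling back to SMC weights")
        return EnsembleWeights(weights=w_smc.weights, provenance="smc_pbma", gamma=w_smc.gamma)
    return EnsembleWeights(weights=prod / total, provenance="smc_pbma", gamma=w_smc.gamma)


def ensemble_predict(per_model_auc: np.ndarray, w: EnsembleWeights) -> float:
    """Weighted arithmetic mean of the per-model AUC predictions."""
    auc = np.asarray(per_model_auc, dtype=float)
    if auc.shape != w.weights.shape:
        raise ValueError("prediction vector and weights must have equal length")
    if np.any(~np.isfinite(auc) & (w.weights > 0)):
        raise ValueError("non-finite model prediction carries nonzero weight")
    return float(np.sum(np.where(w.weights > 0, auc * w.weights, 0.0)))


@dataclass(frozen=True)
class ConfidenceResult:
    """Total latent density at a query plus the low-confidence flag."""

    total_density: float
    low_confidence: bool
    threshold: float | None


def confidence_score(
    latent_densities: list, encoder, x, threshold: float | None = None
) -> ConfidenceResult:
    """Sum of natural-scale latent densities; low values mean the point had
    low density under every model's domain and no model is trustworthy."""
    z = encoder.encode(x)
    logdens = _logdens_matrix(latent_densities, np.atleast_2d(z))[0]
    total = float(np.sum(np.exp(logdens[np.isfinite(logdens)])))
    flag = bool(threshold is not None and total < threshold)
    return ConfidenceResult(total_density=total, low_confidence=flag, threshold=threshold)


def confidence_threshold(
    latent_densities: list, encoder, X: np.ndarray, quantile: float = 0.01
) -> float:
    """Flagging threshold: a low quantile (default 1st percentile) of the
    cohort's own total-density scores."""
    Z = encoder.encode(np.atleast_2d(np.asarray(X, dtype=float)))
    logdens = _logdens_matrix(latent_densities, Z)
    totals = np.sum(np.where(np.isfinite(logdens), np.exp(logdens), 0.0), axis=1)
    return float(np.quantile(totals, quantile))
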