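"""Support densities: each model's training-domain density over covariates.

Covariates are z-scored with a standardizer pooled across all model
summaries before any density is fit, so that no covariate's scale dominates;
log-densities are reported in original units via the Jacobian of the
standardization (a shared constant, so densities remain comparable across
models).

Two forms are provided:
- ``gaussian_moment_matched``: diagonal multivariate Gaussian matching a
  published per-covariate mean/SD summary exactly.
- ``kde``: product-Gaussian kernel density estimate over retained samples
  with a per-dimension bandwidth (Scott's or Silverman's rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .pk import COVARIATE_NAMES, CovariateVector
from .zoo import DemographicSummary

__all__ = [
    "Standardizer",
    "DiagKDE",
    "SupportDensity",
    "pooled_standardizer",
    "fit_gaussian_support",
    "fit_kde_support",
    "logpdf",
    "sample_support",
    "save_density",
    "load_density",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass(frozen=True)
class Standardizer:
    """Affine z-scoring map z = (x - loc) / scale with its log-Jacobian."""

    loc: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "loc", np.asarray(self.loc, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("standardizer scales must be strictly positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.loc) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.loc

    @property
    def log_jacobian(self) -> float:
        """log |dz/dx| — added to standardized-space log-densities to report
        densities per original unit."""
        return float(-np.sum(np.log(self.scale)))

    def to_dict(self) -> dict:
        return {"loc": self.loc.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(loc=np.array(d["loc"]), scale=np.array(d["scale"]))


def pooled_standardizer(summaries: list[DemographicSummary]) -> Standardizer:
    """Standardizer from the equal-weight mixture of the model populations.

    Mixture mean = average of component means; mixture variance = average of
    (sd^2 + mean^2) minus squared mixture mean, which inflates the scale to
    cover all components.
    """
    means = np.stack([s.mean_array() for s in summaries])
    sds = np.stack([s.sd_array() for s in summaries])
    mix_mean = means.mean(axis=0)
    mix_var = (sds**2 + means**2).mean(axis=0) - mix_mean**2
    return Standardizer(loc=mix_mean, scale=np.sqrt(mix_var))


class DiagKDE:
    """Product-Gaussian KDE with a per-dimension bandwidth vector."""

    def __init__(self, samples: np.ndarray, bandwidth: np.ndarray):
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        bandwidth = np.asarray(bandwidth, dtype=float)
        if np.any(bandwidth <= 0):
            raise ValueError("bandwidths must be strictly positive")
        if bandwidth.shape != (samples.shape[1],):
            raise ValueError("one bandwidth per dimension required")
        self.samples = samples
        self.bandwidth = bandwidth

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def dim(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_rule(cls, samples: np.ndarray, rule: str = "scott") -> "DiagKDE":
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        n, d = samples.shape
        sd = samples.std(axis=0, ddof=1) if n > 1 else np.ones(d)
        sd = np.where(sd > 0, sd, 1.0)
        if rule == "scott":
            factor = n ** (-1.0 / (d + 4))
        elif rule == "silverman":
            factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
        else:
            raise ValueError(f"unknown bandwidth rule {rule!r}")
        return cls(samples, sd * factor)

    def logpdf(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        const = -0.5 * self.dim * _LOG2PI - np.sum(np.log(self.bandwidth)) - np.log(self.n)
        out = np.empty(Z.shape[0])
        # chunk queries so the (q, n, d) intermediate stays small
        chunk = max(1, int(4e6 / max(self.n * self.dim, 1)))
        for start in range(0, Z.shape[0], chunk):
            zb = Z[start : start + chunk]
            diff = (zb[:, None, :] - self.samples[None, :, :]) / self.bandwidth
            kern = -0.5 * np.sum(diff**2, axis=2)
            out[start : start + chunk] = logsumexp(kern, axis=1) + const
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(self.n, size=n)
        return self.samples[idx] + rng.normal(size=(n, self.dim)) * self.bandwidth


class SupportDensity:
    """A model's covariate-domain density p_j^X, evaluable and samplable.

    Internally fit in standardized covariate space; `logpdf` reports
    log-density per original covariate unit.
    """

    def __init__(
        self,
        model_id: str,
        form: str,
        standardizer: Standardizer,
        *,
        mean_z: np.ndarray | None = None,
        sd_z: np.ndarray | None = None,
        kde: DiagKDE | None = None,
    ):
        if form not in ("gaussian_moment_matched", "kde"):
            raise ValueError(f"unknown support-density form {form!r}")
        self.model_id = model_id
        self.form = form
        self.standardizer = standardizer
        self.mean_z = None if mean_z is None else np.asarray(mean_z, dtype=float)
        self.sd_z = None if sd_z is None else np.asarray(sd_z, dtype=float)
        self.kde = kde
        if form == "gaussian_moment_matched":
            if self.mean_z is None or self.sd_z is None:
                raise ValueError("gaussian form requires mean_z and sd_z")
            if np.any(self.sd_z <= 0):
                raise ValueError("gaussian SDs must be strictly positive")
        else:
            if kde is None:
                raise ValueError("kde form requires a fitted DiagKDE")

    @property
    def dim(self) -> int:
        return len(COVARIATE_NAMES)

    def logpdf_z(self, Z: np.ndarray) -> np.ndarray:
        """Log-density in standardized space (no Jacobian term)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.form == "gaussian_moment_matched":
            u = (Z - self.mean_z) / self.sd_z
            return (
                -0.5 * np.sum(u**2, axis=1)
                - 0.5 * self.dim * _LOG2PI
                - np.sum(np.log(self.sd_z))
            )
        return self.kde.logpdf(Z)

    def logpdf(self, x) -> np.ndarray | float:
        """Log-density per original covariate unit at x (vector or matrix)."""
        if isinstance(x, CovariateVector):
            x = x.as_array()
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        Z = self.standardizer.transform(np.atleast_2d(x))
        out = self.logpdf_z(Z) + self.standardizer.log_jacobian
        return float(out[0]) if single else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n covariate rows in original units."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.form == "gaussian_moment_matched":
            Z = self.mean_z + rng.normal(size=(n, self.dim)) * self.sd_z
        else:
            Z = self.kde.sample(n, rng)
        return self.standardizer.inverse(Z)

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "form": self.form,
            "standardizer": self.standardizer.to_dict(),
        }
        if self.form == "gaussian_moment_matched":
            d["parameters"] = {"mean_z": self.mean_z.tolist(), "sd_z": self.sd_z.tolist()}
        else:
            d["parameters"] = {
                "samples_z": self.kde.samples.tolist(),
                "bandwidth": self.kde.bandwidth.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SupportDensity":
        std = Standardizer.from_dict(d["standardizer"])
        p = d["parameters"]
        if d["form"] == "gaussian_moment_matched":
            return cls(
                d["model_id"], d["form"], std,
                mean_z=np.array(p["mean_z"]), sd_z=np.array(p["sd_z"]),
            )
        return cls(
            d["model_id"], d["form"], std,
            kde=DiagKDE(np.array(p["samples_z"]), np.array(p["bandwidth"])),
        )


def fit_gaussian_support(
    summary: DemographicSummary,
    model_id: str | None = None,
    standardizer: Standardizer | None = None,
) -> SupportDensity:
    """Moment-matched diagonal Gaussian from a per-covariate mean/SD summary."""
    for name in COVARIATE_NAMES:
        if name not in summary.mean:
            raise ValueError(f"summary missing covariate '{name}'")
    if standardizer is None:
        standardizer = pooled_standardizer([summary])
    mean_z = standardizer.transform(summary.mean_array())
    sd_z = summary.sd_array() / standardizer.scale
    return SupportDensity(
        model_id or summary.model_id,
        "gaussian_moment_matched",
        standardizer,
        mean_z=mean_z,
        sd_z=sd_z,
    )


def fit_kde_support(
    samples: np.ndarray,
    model_id: str,
    bandwidth_rule: str = "scott",
    standardizer: Standardizer | None = None,
) -> SupportDensity:
    """Gaussian-kernel KDE over raw covariate samples (n >= 10)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 10:
        raise ValueError(
            "fewer than 10 samples: use fit_gaussian_support on a moment summary instead"
        )
    if standardizer is None:
        standardizer = Standardizer(
            loc=samples.mean(axis=0),
            scale=np.where(samples.std(axis=0) > 0, samples.std(axis=0), 1.0),
        )
    Z = standardizer.transform(samples)
    kde = DiagKDE.from_rule(Z, bandwidth_rule)
    return SupportDensity(model_id, "kde", standardizer, kde=kde)


def logpdf(density: SupportDensity, x) -> float | np.ndarray:
    """Functional alias for :meth:`SupportDensity.logpdf`."""
    return density.logpdf(x)


def sample_support(density: SupportDensity, n: int, rng: np.random.Generator) -> np.ndarray:
    """Functional alias for :meth:`SupportDensity.sample`."""
    return density.sample(n, rng)


def save_density(density: SupportDensity, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(density.to_dict(), fh, indent=2)


def load_density(path) -> SupportDensity:
    with open(path, encoding="utf-8") as fh:
        return SupportDensity.from_dict(json.load(fh))
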