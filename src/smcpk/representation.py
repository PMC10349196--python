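"""Learned low-dimensional representation f_theta of the covariate space.

A small feed-forward autoencoder (plain or variational) is trained on the
unlabeled test-cohort covariates together with samples drawn from every
model's support density. An auxiliary linear classification head on the
latent predicts which model's support a labeled sample came from
(cross-entropy, weight ``aux_weight``); this nudges the latent space to
separate model domains by transferability while the reconstruction term
keeps it faithful to the covariates. Test-cohort rows are unlabeled and
contribute reconstruction (and KL) terms only.

With only four covariates the representation step is optional: a
:class:`PassthroughEncoder` (identity after standardization) runs the full
pipeline with no learned map and is the oracle route in tests.

The network is implemented directly on numpy (manual backprop, Adam); the
sizes involved (4 -> 16 -> 2) need nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .density import Standardizer
from .pk import CovariateVector

__all__ = [
    "EncoderConfig",
    "Encoder",
    "PassthroughEncoder",
    "fit_encoder",
    "encode",
    "passthrough_encoder",
    "save_encoder",
    "load_encoder",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    """Training configuration for the representation network.

    aux_weight is the cross-entropy weight of the domain-classification
    head (0 disables it); kl_weight applies in ``vae`` mode only.
    """

    latent_dim: int = 2
    mode: str = "ae"  # "ae" | "vae"
    aux_weight: float = 0.1
    epochs: int = 500
    batch_size: int = 64
    lr: float = 1e-3
    hidden: int = 16
    activation: str = "tanh"  # "tanh" | "linear"
    kl_weight: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ae", "vae"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def _act(pre: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(pre) if kind == "tanh" else pre


def _act_grad(out: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - out**2 if kind == "tanh" else np.ones_like(out)


class Encoder:
    """Trained encoder/decoder pair; ``encode`` is deterministic (VAE mode
    uses the mean head at inference)."""

    def __init__(
        self,
        config: EncoderConfig,
        standardizer: Standardizer,
        params: dict,
        training_log: list[dict],
        n_classes: int,
    ):
        self.config = config
        self.standardizer = standardizer
        self.params = params
        self.training_log = training_log
        self.n_classes = n_classes

    @property
    def input_dim(self) -> int:
        return self.params["W1"].shape[0]

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def _prepare(self, x):
        if isinstance(x, CovariateVector):
            x = x.as_array()
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input to encoder")
        return self.standardizer.transform(X), single

    def encode(self, x) -> np.ndarray:
        Z, single = self._prepare(x)
        p = self.params
        h1 = _act(Z @ p["W1"] + p["b1"], self.config.activation)
        mu = h1 @ p["W2"] + p["b2"]
        return mu[0] if single else mu

    def reconstruct(self, x) -> np.ndarray:
        """Decode(encode(x)) back in original covariate units."""
        Z, single = self._prepare(x)
        p = self.params
        h1 = _act(Z @ p["W1"] + p["b1"], self.config.activation)
        mu = h1 @ p["W2"] + p["b2"]
        h2 = _act(mu @ p["W3"] + p["b3"], self.config.activation)
        xhat = h2 @ p["W4"] + p["b4"]
        out = self.standardizer.inverse(xhat)
        return out[0] if single else out


class PassthroughEncoder:
    """Identity representation: encode(x) = standardized x."""

    def __init__(self, standardizer: Standardizer):
        self.standardizer = standardizer
        self.config = None

    @property
    def input_dim(self) -> int:
        return len(self.standardizer.loc)

    @property
    def latent_dim(self) -> int:
        return self.input_dim

    def encode(self, x) -> np.ndarray:
        if isinstance(x, CovariateVector):
            x = x.as_array()
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        Z = self.standardizer.transform(np.atleast_2d(x))
        return Z[0] if single else Z


def passthrough_encoder(
    standardizer: Standardizer | None = None, input_dim: int = 4
) -> PassthroughEncoder:
    """Passthrough encoder; with no standardizer given, an identity one."""
    if standardizer is None:
        standardizer = Standardizer(loc=np.zeros(input_dim), scale=np.ones(input_dim))
    return PassthroughEncoder(standardizer)


def _init_params(rng, d, h, L, K, mode):
    def glorot(m, n):
        return rng.normal(0.0, np.sqrt(2.0 / (m + n)), size=(m, n))

    params = {
        "W1": glorot(d, h), "b1": np.zeros(h),
        "W2": glorot(h, L), "b2": np.zeros(L),
        "W3": glorot(L, h), "b3": np.zeros(h),
        "W4": glorot(h, d), "b4": np.zeros(d),
        "Wc": glorot(L, max(K, 1)), "bc": np.zeros(max(K, 1)),
    }
    if mode == "vae":
        params["W2v"] = glorot(h, L)
        params["b2v"] = np.zeros(L)
    return params


def fit_encoder(
    test_features: np.ndarray,
    support_samples: dict[str, np.ndarray],
    config: EncoderConfig | None = None,
) -> Encoder:
    """Train the representation on test covariates + per-model support draws.

    Parameters
    ----------
    test_features : (n, d) unlabeled covariate matrix (original units).
    support_samples : mapping model_id -> (m_j, d) covariate samples drawn
        from that model's support density; rows carry the model label for
        the auxiliary head.
    """
    config = config or EncoderConfig()
    test_features = np.atleast_2d(np.asarray(test_features, dtype=float))
    model_ids = list(support_samples)
    blocks = [test_features] + [
        np.atleast_2d(np.asarray(support_samples[m], dtype=float)) for m in model_ids
    ]
    X_all = np.vstack(blocks)
    if not np.all(np.isfinite(X_all)):
        raise ValueError("non-finite values in encoder training data")
    d = X_all.shape[1]
    if config.latent_dim > d:
        raise ValueError("latent_dim must not exceed input_dim")
    if X_all.shape[0] < 50:
        raise ValueError("need at least 50 training rows")
    labels = np.concatenate(
        [np.full(test_features.shape[0], -1, dtype=int)]
        + [np.full(blocks[j + 1].shape[0], j, dtype=int) for j in range(len(model_ids))]
    )
    K = len(model_ids)

    sd = X_all.std(axis=0)
    standardizer = Standardizer(loc=X_all.mean(axis=0), scale=np.where(sd > 0, sd, 1.0))
    Xz = standardizer.transform(X_all)

    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, d, config.hidden, config.latent_dim, K, config.mode)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0
    use_aux = config.aux_weight > 0 and K > 0
    log: list[dict] = []
    n = Xz.shape[0]
    act = config.activation

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_recon = ep_aux = ep_kl = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = Xz[idx], labels[idx]
            B = Xb.shape[0]
            grads = {k: np.zeros_like(v) for k, v in params.items()}

            h1 = _act(Xb @ params["W1"] + params["b1"], act)
            mu = h1 @ params["W2"] + params["b2"]
            if config.mode == "vae":
                lv = h1 @ params["W2v"] + params["b2v"]
                epsn = rng.normal(size=mu.shape)
                z = mu + np.exp(0.5 * lv) * epsn
            else:
                z = mu
            h2 = _act(z @ params["W3"] + params["b3"], act)
            xhat = h2 @ params["W4"] + params["b4"]

            recon = float(np.sum((xhat - Xb) ** 2) / B)
            d_xhat = 2.0 * (xhat - Xb) / B
            grads["W4"] = h2.T @ d_xhat
            grads["b4"] = d_xhat.sum(axis=0)
            d_h2 = d_xhat @ params["W4"].T
            d_pre2 = d_h2 * _act_grad(h2, act)
            grads["W3"] = z.T @ d_pre2
            grads["b3"] = d_pre2.sum(axis=0)
            d_z = d_pre2 @ params["W3"].T

            aux_loss = 0.0
            lab = yb >= 0
            if use_aux and np.any(lab):
                zl = z[lab]
                logits = zl @ params["Wc"] + params["bc"]
                logits = logits - logits.max(axis=1, keepdims=True)
                expl = np.exp(logits)
                probs = expl / expl.sum(axis=1, keepdims=True)
                nl = zl.shape[0]
                onehot = np.zeros_like(probs)
                onehot[np.arange(nl), yb[lab]] = 1.0
                aux_loss = float(-np.sum(onehot * np.log(probs + 1e-300)) / nl)
                d_logits = config.aux_weight * (probs - onehot) / nl
                grads["Wc"] = zl.T @ d_logits
                grads["bc"] = d_logits.sum(axis=0)
                d_z_lab = d_logits @ params["Wc"].T
                d_z = d_z.copy()
                d_z[lab] += d_z_lab

            kl_loss = 0.0
            if config.mode == "vae":
                kl_loss = float(0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / B)
                d_mu = d_z + config.kl_weight * mu / B
                d_lv = d_z * epsn * 0.5 * np.exp(0.5 * lv) + config.kl_weight * 0.5 * (
                    np.exp(lv) - 1.0
                ) / B
                grads["W2v"] = h1.T @ d_lv
                grads["b2v"] = d_lv.sum(axis=0)
                d_h1 = d_mu @ params["W2"].T + d_lv @ params["W2v"].T
            else:
                d_mu = d_z
                d_h1 = d_mu @ params["W2"].T
            grads["W2"] = h1.T @ d_mu
            grads["b2"] = d_mu.sum(axis=0)
            d_pre1 = d_h1 * _act_grad(h1, act)
            grads["W1"] = Xb.T @ d_pre1
            grads["b1"] = d_pre1.sum(axis=0)

            t_step += 1
            for k in params:
                g = grads[k]
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g**2
                mhat = adam_m[k] / (1 - beta1**t_step)
                vhat = adam_v[k] / (1 - beta2**t_step)
                params[k] = params[k] - config.lr * mhat / (np.sqrt(vhat) + eps)

            ep_recon += recon
            ep_aux += aux_loss
            ep_kl += kl_loss
            n_batches += 1

        rec = ep_recon / n_batches
        aux = ep_aux / n_batches
        kl = ep_kl / n_batches
        total = rec + config.aux_weight * aux + (
            config.kl_weight * kl if config.mode == "vae" else 0.0
        )
        log.append({"epoch": epoch, "total": total, "recon": rec, "aux": aux, "kl": kl})

    return Encoder(config, standardizer, params, log, n_classes=K)


def encode(encoder, x) -> np.ndarray:
    """Functional alias: latent representation of x (vector or matrix)."""
    return encoder.encode(x)


def save_encoder(encoder: Encoder, path) -> None:
    if isinstance(encoder, PassthroughEncoder):
        raise ValueError("passthrough encoders are stateless; nothing to save")
    blob = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(encoder.config),
        "standardizer": encoder.standardizer.to_dict(),
        "n_classes": encoder.n_classes,
        "params": {k: v.tolist() for k, v in encoder.params.items()},
        "training_log": encoder.training_log,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(blob, fh)


def load_encoder(path) -> Encoder:
    with open(path, encoding="utf-8") as fh:
        blob = json.load(fh)
    version = blob.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported encoder file version {version!r}")
    return Encoder(
        EncoderConfig(**blob["config"]),
        Standardizer.from_dict(blob["standardizer"]),
        {k: np.array(v) for k, v in blob["params"].items()},
        blob["training_log"],
        n_classes=blob["n_classes"],
    )
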