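"""Synthetic model zoo: a configurable set of population-PK models whose
covariate training domains (demographic summaries) are distinct.

Published vancomycin models come from different subpopulations (extremely
obese, post cardiac surgery, trauma, intensive care, septic, general ward);
the default six archetypes here emulate that structure — partially
overlapping Gaussian covariate domains over (age, height, weight, crcl) and
covariate laws whose typical clearance/volume parameters differ — without
reproducing any published parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import COVARIATE_NAMES, CovariateLaw, PopPKModel

__all__ = [
    "DemographicSummary",
    "ZooModelConfig",
    "make_model_zoo",
    "default_zoo",
    "separated_zoo",
    "overlapping_zoo",
]


@dataclass(frozen=True)
class DemographicSummary:
    """Per-covariate mean and SD of a model's training population."""

    model_id: str
    mean: dict
    sd: dict

    def __post_init__(self) -> None:
        for name in COVARIATE_NAMES:
            if name not in self.mean or name not in self.sd:
                raise ValueError(f"demographic summary missing covariate '{name}'")
            if self.sd[name] <= 0:
                raise ValueError(f"non-positive SD for covariate '{name}'")

    def mean_array(self) -> np.ndarray:
        return np.array([self.mean[k] for k in COVARIATE_NAMES], dtype=float)

    def sd_array(self) -> np.ndarray:
        return np.array([self.sd[k] for k in COVARIATE_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {k: {"mean": self.mean[k], "sd": self.sd[k]} for k in COVARIATE_NAMES}

    @classmethod
    def from_dict(cls, model_id: str, d: dict) -> "DemographicSummary":
        return cls(
            model_id=model_id,
            mean={k: d[k]["mean"] for k in COVARIATE_NAMES},
            sd={k: d[k]["sd"] for k in COVARIATE_NAMES},
        )


@dataclass(frozen=True)
class ZooModelConfig:
    """One zoo entry: demographic moments plus covariate-law parameters."""

    model_id: str
    demographics: dict  # covariate -> (mean, sd)
    cl_typical: float
    v_typical: float
    cl_crcl_exp: float = 0.75
    cl_weight_exp: float = 0.0
    v_weight_exp: float = 1.0
    omega_cl: float = 0.25
    omega_v: float = 0.2
    sigma_prop: float = 0.1
    sigma_add: float = 1.0


# Six archetypes mirroring the kinds of subpopulations behind published
# vancomycin models. Values are field-plausible, not any published model's.
_DEFAULT_ARCHETYPES: tuple[ZooModelConfig, ...] = (
    ZooModelConfig(
        "obese",
        {"age": (45, 12), "height": (170, 8), "weight": (125, 18), "crcl": (115, 25)},
        cl_typical=4.6, v_typical=62.0, cl_crcl_exp=0.7, cl_weight_exp=0.4,
    ),
    ZooModelConfig(
        "cardiac_surgery",
        {"age": (66, 9), "height": (171, 8), "weight": (80, 12), "crcl": (68, 20)},
        cl_typical=3.0, v_typical=55.0, cl_crcl_exp=0.8,
    ),
    ZooModelConfig(
        "trauma",
        {"age": (34, 11), "height": (176, 8), "weight": (78, 11), "crcl": (125, 24)},
        cl_typical=5.1, v_typical=50.0, cl_crcl_exp=0.65, cl_weight_exp=0.2,
    ),
    ZooModelConfig(
        "intensive_care",
        {"age": (61, 14), "height": (170, 9), "weight": (83, 15), "crcl": (58, 22)},
        cl_typical=2.7, v_typical=78.0, cl_crcl_exp=0.85, v_weight_exp=0.8,
    ),
    ZooModelConfig(
        "septic",
        {"age": (56, 15), "height": (171, 9), "weight": (86, 14), "crcl": (82, 28)},
        cl_typical=3.5, v_typical=82.0, cl_crcl_exp=0.75, v_weight_exp=0.9,
    ),
    ZooModelConfig(
        "hospitalized",
        {"age": (58, 17), "height": (169, 9), "weight": (74, 12), "crcl": (86, 24)},
        cl_typical=3.9, v_typical=48.0, cl_crcl_exp=0.75,
    ),
)


def _build_entry(cfg: ZooModelConfig) -> tuple[PopPKModel, DemographicSummary]:
    summary = DemographicSummary(
        model_id=cfg.model_id,
        mean={k: float(v[0]) for k, v in cfg.demographics.items()},
        sd={k: float(v[1]) for k, v in cfg.demographics.items()},
    )
    law = CovariateLaw(
        cl_typical=cfg.cl_typical,
        v_typical=cfg.v_typical,
        cl_crcl_exp=cfg.cl_crcl_exp,
        cl_weight_exp=cfg.cl_weight_exp,
        v_weight_exp=cfg.v_weight_exp,
    )
    model = PopPKModel(
        model_id=cfg.model_id,
        law=law,
        omega_cl=cfg.omega_cl,
        omega_v=cfg.omega_v,
        sigma_prop=cfg.sigma_prop,
        sigma_add=cfg.sigma_add,
    )
    return model, summary


def make_model_zoo(
    configs: list[ZooModelConfig] | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[PopPKModel, DemographicSummary]]:
    """Build (model, demographic summary) pairs from explicit configs.

    With configs=None the six default archetypes are returned. The result is
    fully determined by the configs; `rng` is accepted for interface symmetry
    with stochastic zoo builders and is unused for explicit configs.
    """
    if configs is None:
        configs = list(_DEFAULT_ARCHETYPES)
    if len(configs) < 2:
        raise ValueError("a model zoo needs at least 2 models")
    return [_build_entry(c) for c in configs]


def default_zoo() -> list[tuple[PopPKModel, DemographicSummary]]:
    """The six-archetype default zoo."""
    return make_model_zoo()


def separated_zoo(
    n_models: int = 3,
    separation: float = 4.0,
    base_sd: float | None = None,
) -> list[tuple[PopPKModel, DemographicSummary]]:
    """A zoo with well-separated covariate domains and distinct dynamics.

    Domain centroids are spaced `separation` pooled SDs apart along the
    weight and crcl axes; clearance/volume laws differ strongly across
    models so that applying the wrong model yields clearly biased AUCs.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    sds = {"age": 8.0, "height": 7.0, "weight": 9.0, "crcl": 15.0}
    if base_sd is not None:
        sds = {k: base_sd for k in sds}
    cl_typ = np.linspace(2.0, 6.5, n_models)
    v_typ = np.linspace(45.0, 90.0, n_models)
    configs = []
    for i in range(n_models):
        offset = (i - (n_models - 1) / 2) * separation
        configs.append(
            ZooModelConfig(
                model_id=f"domain_{i}",
                demographics={
                    "age": (50.0, sds["age"]),
                    "height": (170.0, sds["height"]),
                    "weight": (85.0 + offset * sds["weight"], sds["weight"]),
                    "crcl": (90.0 + offset * sds["crcl"], sds["crcl"]),
                },
                cl_typical=float(cl_typ[i]),
                v_typical=float(v_typ[i]),
                cl_crcl_exp=0.6 + 0.15 * i,
                cl_weight_exp=0.1 * i,
            )
        )
    return make_model_zoo(configs)


def overlapping_zoo(
    n_models: int = 3,
    poor_model: bool = True,
) -> list[tuple[PopPKModel, DemographicSummary]]:
    """A zoo whose covariate domains fully overlap (identical summaries).

    With `poor_model=True` an extra model with the same domain but a badly
    miscalibrated clearance law is appended; it is a pure predictor (it
    should not generate patients) and exercises the failure mode where
    density-based weighting cannot see performance differences.
    """
    demo = {"age": (55.0, 15.0), "height": (170.0, 9.0), "weight": (80.0, 13.0), "crcl": (85.0, 25.0)}
    cl_typ = np.linspace(3.2, 4.2, n_models)
    configs = [
        ZooModelConfig(
            model_id=f"overlap_{i}",
            demographics=demo,
            cl_typical=float(cl_typ[i]),
            v_typical=60.0,
            cl_crcl_exp=0.7 + 0.05 * i,
        )
        for i in range(n_models)
    ]
    if poor_model:
        configs.append(
            ZooModelConfig(
                model_id="poor",
                demographics=demo,
                cl_typical=11.0,  # grossly over-predicts clearance
                v_typical=25.0,
                cl_crcl_exp=0.2,
            )
        )
    return make_model_zoo(configs)
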