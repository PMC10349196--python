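# Methods

This note documents the models, defaults, and design choices behind
`smcpk`, and what its synthetic experiments do and do not demonstrate.

## The problem

Several PopPK models exist for the same drug, each developed in a distinct
subpopulation. A model applied outside its training domain extrapolates,
often badly — the covariate-shift failure mode of global model averaging.
SMC weights models per patient by the density of the patient's covariates
under each model's training domain; the weights exist before any drug
level is measured, so a-priori dose individualization is possible where
performance-based averaging degenerates to the naive ensemble.

## Pharmacokinetic engine

Structural model: one compartment, zero-order IV infusion, first-order
elimination, linear kinetics with superposition over doses. This is the
standard minimal description for vancomycin-like drugs; two-compartment
kinetics are deliberately out of scope. Individual parameters:

    CL_i = θ_CL (crcl/100)^θ_1 (weight/70)^θ_2 · exp(η_CL)     [L/h]
    V_i  = θ_V (weight/70)^θ_3 · exp(η_V)                      [L]

with η ~ N(0, ω²) elementwise (log-normal IIV on CL and V only) and
combined residual error var = (σ_prop·pred)² + σ_add² on concentrations.
Concentration and windowed AUC have exact closed forms (per-dose infusion
and washout segments integrated analytically), so no quadrature is used at
run time; tests verify the closed forms against adaptive quadrature and
ODE integration.

Defaults: regimen 1000 mg infused over 1 h every 12 h, 4 doses; horizon
48 h; AUC target window 24–48 h (the second, near-steady-state day).
Sparse sampling uses fixed trough-oriented times {11.5, 23.5, 35.5} h for
1–3 observations; a fixed design removes a nuisance source of variance
from method comparisons.

MAP estimation maximizes the penalized log-likelihood (Gaussian residuals
plus the N(0, ω²) prior on η) with L-BFGS-B from η = 0; zero observations
return the prior mode exactly, ω = 0 pins a parameter at its typical
value, and the convergence status is surfaced on the result. The
experiment harness uses a vectorized damped-Newton variant
(`map_estimate_batch`, central-difference derivatives, per-patient
backtracking) that agrees with the scalar optimizer to ~1e-4 and makes
20-seed cohort studies run in seconds.

## Synthetic model zoo

Published vancomycin models are cited in the literature by subpopulation
but their parameterizations are not reproduced here; the zoo emulates the
*structure* of that model family. The default six archetypes (obese,
cardiac surgery, trauma, intensive care, septic, hospitalized) have
field-plausible demographic moments (e.g. the obese cohort: weight
125 ± 18 kg) and covariate laws whose typical clearance (2.7–5.1 L/h) and
volume (48–82 L) differ enough that applying the wrong model produces
clearly biased AUCs. Two purpose-built zoos support the stress tests:
`separated_zoo` (domain centroids ≥ 4 pooled SD apart along weight/crcl,
strongly distinct laws) and `overlapping_zoo` (identical demographics,
optionally plus one grossly miscalibrated "poor" model that never
generates patients).

## Support densities

Covariates are z-scored with a standardizer pooled across all model
summaries (equal-weight mixture moments) before fitting, so no covariate's
scale dominates; log-densities add the Jacobian of this affine map and are
therefore in original units and comparable across models. Gaussian
supports are diagonal-covariance because published demographic tables
rarely report correlations. Densities are not truncated at zero —
simulation clamps covariates to positive bounds instead, and the mass
below zero is negligible for realistic summaries. KDE supports use a
product-Gaussian kernel with per-dimension Scott bandwidth
(σ_k n^{-1/(d+4)}); Silverman's rule is available.

## Representation

A 4→16→latent feed-forward autoencoder (tanh; linear option), decoder
mirrored, trained by Adam (lr 1e-3, batch 64, 500 epochs default) on the
unlabeled test covariates plus labeled draws from every support. The
auxiliary loss — the part the literature leaves open — is chosen here as a
linear classification head on the latent predicting which model's support
a sample came from, cross-entropy weighted by λ (default 0.1): it directly
encourages domains to separate by provenance, is ablatable (λ = 0 recovers
the plain autoencoder), and the interface accepts alternatives. VAE mode
adds a KL term (weight 0.1) and uses the posterior mean at inference so
encoding stays deterministic. Default latent dimension is 2; with only
four covariates the passthrough (standardize-only) encoder is a fully
supported alternative and is the oracle route in tests, where SMC weights
must match closed-form covariate-space density ratios.

The network is implemented directly on numpy with manual backprop; at
these sizes a deep-learning framework would add nothing but weight.
Training is bit-reproducible given the seed. Numerical note: the
"smoothed monotonicity" check on training curves uses a 10-epoch moving
average and tolerates upticks up to 1% of the final loss — minibatch noise
under Adam makes strictly monotone averages unrealistic.

## Weights

Latent densities p_j^Z are KDEs over `n_samples` (default 2000) encoded
support draws. The SMC weight is the displayed ratio with densities on the
natural scale. Because densities carry units, an *absolute* γ would make
the outlier behavior depend on covariate scaling; the default therefore
interprets γ relative to the per-query maximum density (all densities are
rescaled so the largest is 1 before γ = 1e-6 is added). This is scale-free,
preserves the far-outlier limit w → 1/N exactly, and leaves the weights
within γ·N of the generative posterior P(model | x) under the hierarchical
reading; the literal absolute form is available via `gamma_mode="absolute"`.
Log-densities are used internally with shared max-subtraction, so
underflow cannot zero out a query.

PBMA maps any supported score (BIC default; AIC, log-likelihood as −2·ll,
variance-scaled SSE) through softmax(−score/2) with max-subtraction. For a
fixed published model the parameter count k is the number of
individual-level parameters optimized at prediction time (the η dimension,
2), since only individualization is fitted to the observations; n is the
number of observations. Zero observations yield an "uninformative"
evidence object and exactly uniform weights. SMC × PBMA combine as
elementwise product renormalized (prior × evidence); an identically zero
product falls back to the SMC weights with a logged warning. Ties are
never broken by selection — equal inputs give equal weights everywhere.

The confidence score is Σ_j p_j^Z at the encoded query; the low-confidence
flag uses the 1st percentile of the evaluation cohort's own scores as its
default threshold.

## Cohort simulation

The global covariate population is the pooled mixture of the zoo's
demographics (mixture mean; mixture SD, which inflates to cover all
components), clamped to positive bounds. Two regimes:

- **original** — each model generates an equal share of patients whose
  covariates come from the global population regardless of domain;
- **realistic** — the generating model is drawn with probability
  proportional to its support density at the patient's covariates.

`rejection_subsample` is the subsampling counterpart of the realistic
regime: it keeps patients whose argmax-likelihood model matches their
generator. Exact argmax ties discard the patient (a conservative reading;
ties are counted and logged). The retained count is whatever survives —
it is reported, not forced to a target size.

## Evaluation

Relative bias = mean of 100·(pred−truth)/truth (signed in machine output;
tabulations elsewhere often print magnitudes) and relative RMSE =
100·sqrt(mean of squared relative errors), with patient-level
nonparametric bootstrap SEs (B = 200 default; one shared index matrix per
level so method contrasts are paired). The experiment harness produces the
(N models + 4 methods) × 4 observation-level table end-to-end from one
seed; a-priori per-model predictions use η = 0, and with observations each
model's prediction and its PBMA evidence share one MAP fit per patient.

Experiment sizes in the shipped tests (realistic cohorts of 800–1500
patients, 20 seeds; latent KDEs of 2000 draws) were chosen as the smallest
sizes at which the between-method contrasts are far clearer than their
bootstrap noise.

## What the synthetic experiments show — and don't

The generator implements exactly the covariate-shift structure SMC
assumes: distinct Gaussian domains, a generating process tied to domain
density, and models that are correct inside their own domain. Passing
tests therefore demonstrate that the pipeline recovers the generative
posterior and converts it into better instance-wise predictions *when that
assumption holds*, and that the PBMA combination repairs SMC when it does
not (fully overlapping domains with a poor model). They do not certify
performance on real cohorts, where domains are non-Gaussian and
correlated, demographic summaries are incomplete, residual-error models
are misspecified, and published models differ structurally (two
compartments, nonlinear clearance). Known limitations, inherited by
design: no covariate correlations in Gaussian supports, no time-varying
covariates, no saturable elimination, no NONMEM interoperability.
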