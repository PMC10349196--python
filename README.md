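# smcpk — instance-wise ensembling of population-PK models

Many population-pharmacokinetic (PopPK) models often exist for the same
drug, each developed in a different subpopulation (obese patients, cardiac
surgery, trauma, intensive care, …). When a new patient arrives, which
model should drive the dose? Global model-averaging schemes pick one
weighting for everybody, but a model is only trustworthy near the
covariate region it was trained on. **Synthetic Model Combination (SMC)**
weights the candidate models *per patient*, by how plausible that
patient's covariates are under each model's training domain — and it needs
no measured drug concentration to do so, which matters for a-priori dosing
before any level has been drawn.

`smcpk` implements the full SMC pipeline for AUC-guided dosing
(vancomycin-style), together with its comparators and a synthetic
simulation harness:

1. **Support densities** `p_j^X(x)`: each model's training domain over
   (age, height, weight, creatinine clearance), fit as a moment-matched
   diagonal Gaussian from a published demographic summary or as a KDE from
   raw samples.
2. **Representation learning** `f_θ`: a small (variational) autoencoder
   trained on test-cohort covariates plus draws from every support, with an
   auxiliary domain-classification head that pulls model domains apart in
   the latent space. With only four covariates the passthrough
   (standardize-only) encoder is a documented alternative.
3. **Instance-wise weights**: supports are re-modeled in latent space by
   KDE (`p_j^Z`), and each test point gets

   ```
   w_i(x) = (p_i^Z(f_θ(x)) + γ) / Σ_j (p_j^Z(f_θ(x)) + γ)
   ```

   with a small regularizer γ so far outliers fall back to uniform
   weights. The summed density Σ_j p_j^Z also serves as a confidence score:
   patients with low density under *every* domain are flagged.

Comparators: the naive ensemble (w = 1/N), performance-based model
averaging (PBMA, `p(M_i|D) = exp(-BIC_i/2)/Σ_j exp(-BIC_j/2)` with BIC /
AIC / log-likelihood / SSE scores from MAP-fitted individual parameters),
and the SMC × PBMA product combination (SMC as covariate prior, PBMA as
evidence update).

The PK engine is a one-compartment zero-order-infusion model with
power-law covariate effects on clearance and volume, log-normal
inter-individual variability, combined residual error, closed-form
concentration and AUC, and MAP estimation of individual random effects
from sparse (0–3) concentration measurements.

## Worked example

```python
from smcpk import run_experiment, separated_zoo

result = run_experiment(separated_zoo(3), regime="realistic", n_total=500, seed=0)
print(result.results.pivot(index="method", columns="n_obs", values="rrmse").round(1))
```

prints (relative RMSE of day-two AUC predictions, %, by number of
concentration measurements):

```
n_obs         0     1     2     3
method
domain_0  137.1  71.1  39.6  32.3
domain_1   41.9  26.6  17.2  13.6
domain_2   35.7  20.6  14.1  11.7
naive      58.4  33.4  20.0  16.0
pbma       58.4  21.4  14.5  13.2
smc        23.1  15.4  11.1   8.9
smc_pbma   23.1  15.0  11.0   8.9
```

Read it as: with zero observations PBMA has no evidence and collapses to
the naive ensemble, while SMC already halves its error by using the
covariates; once levels are drawn, the SMC × PBMA combination tracks the
better of its two components. The `examples/` directory walks through each
capability (`01_pk_engine.py` … `05_experiment.py`), and the `smcpk` CLI
(`simulate-cohort`, `fit-supports`, `fit-encoder`, `fit-latent`, `predict`,
`run-experiment`, `evaluate`) exposes the same pipeline for shell use with
YAML configs and explicit seeds.

## Layout

- `src/smcpk/pk.py` — PK engine (types, closed forms, MAP estimation)
- `src/smcpk/zoo.py` — synthetic model zoo (six subpopulation archetypes)
- `src/smcpk/density.py` — support densities (Gaussian / KDE, standardized)
- `src/smcpk/representation.py` — autoencoder + passthrough encoder
- `src/smcpk/ensemble.py` — SMC / PBMA / naive / combined weights, confidence
- `src/smcpk/cohort.py` — simulation regimes and sparse observations
- `src/smcpk/evaluation.py` — metrics and the experiment harness
- `src/smcpk/cli.py`, `config.py`, `io.py` — CLI, YAML config, artifact schemas
- `docs/methods.md` — modeling assumptions, defaults, and design choices
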