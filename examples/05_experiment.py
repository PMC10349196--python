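"""Compare all ensembling methods on a simulated realistic cohort.

Simulates patients whose generating model is drawn proportionally to each
model's covariate-domain density, then scores every method's day-two AUC
predictions by relative bias and relative RMSE across 0-3 concentration
measurements.
"""

from smcpk import run_experiment, separated_zoo

result = run_experiment(
    separated_zoo(3),
    regime="realistic",
    n_total=500,
    seed=0,
)

table = result.results
print("relative RMSE (%) by method and number of observations:")
print(
    table.pivot(index="method", columns="n_obs", values="rrmse").round(1).to_string()
)
print("\nrelative bias (%, signed):")
print(
    table.pivot(index="method", columns="n_obs", values="rbias").round(1).to_string()
)
print(
    "\nAt 0 observations PBMA has no evidence and equals the naive ensemble,"
    "\nwhile SMC already exploits the covariates; with observations the"
    "\nSMC x PBMA combination tracks the better of its two components."
)
print(f"\nlow-confidence patients flagged: {result.run_log['n_low_confidence']}")
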