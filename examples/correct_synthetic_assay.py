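"""Simulate a biased bulk fitness assay and correct it.

Generates the standard synthetic protocol (500 variants, 5 assays, 4
timepoints, Poisson sampling at 1e6 reads/sample) with a 40-variant
equal-fitness control set, runs the two-stage bias inference, and reports the
fitness error before/after correction relative to the Poisson-only floor.
"""
import numpy as np

from rebar import RebarConfig, SimulationConfig, run_replicate

config = SimulationConfig(seed=42)
summary, result, truth = run_replicate(config, RebarConfig(seed=42))

print(f"MAE of fitness estimates, raw:        {summary.mae_pre:.4f}")
print(f"MAE of fitness estimates, corrected:  {summary.mae_post:.4f}")
print(f"Poisson-only noise floor (MAE_noise): {summary.mae_noise:.4f}")
print(f"relative error after correction eps:  {summary.epsilon:.3f}")
print(f"bias-induced error removed:           {100 * (1 - summary.epsilon):.1f}%")

r = np.corrcoef(result.bias.u, truth.u_true)[0, 1]
print(f"\ncorr(inferred u, true u) = {r:+.3f}  (sign is a convention)")
for j, assay in enumerate(truth.assays):
    print(
        f"{assay.assay_id}: trend lambda true {truth.lambda_true[j]:+.4f}  "
        f"inferred {np.sign(r) * result.bias.lam[j]:+.4f}"
    )
print(
    "\nMAE_pre >> MAE_noise means bias corrupted the raw slopes; MAE_post"
    "\napproaching the floor means the correction removed most of it."
)
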