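"""Cross-check inferred susceptibilities against the independent SVD oracle.

For an equal-fitness group, the variant-by-assay matrix of fitness errors is
rank one (delta_f = u * lambda), so its first singular vectors estimate the
bias components with no iterative inference. Strong correlation between the
two routes validates the alternating-optimization estimates.
"""
import numpy as np

from rebar import RebarConfig, run_rebar, simulate_dataset, SimulationConfig, svd_bias_oracle

config = SimulationConfig(n_variants=500, control_size=100, seed=60)
dataset, truth = simulate_dataset(config)
result = run_rebar(dataset, truth.control_ids, RebarConfig(seed=0))

idx = result.raw_fits.variant_index(truth.control_ids)
delta = result.raw_fits.slope[idx] - result.raw_fits.slope[idx].mean(axis=0)
u_svd, lam_svd = svd_bias_oracle(delta)

r_methods = np.corrcoef(result.bias.u[idx], u_svd)[0, 1]
r_truth = np.corrcoef(u_svd, truth.u_true[idx])[0, 1]
print(f"corr(iterative u, SVD u) over the group: {abs(r_methods):.3f}")
print(f"corr(SVD u, true u):                     {abs(r_truth):.3f}")
print(
    "\nBoth estimates agree with each other and with the simulated truth;"
    "\nthe SVD route needs a known equal-fitness group, while the iterative"
    "\ninference covers the whole library."
)
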