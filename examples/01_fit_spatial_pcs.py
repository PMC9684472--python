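"""Fit spatially aware factors to a simulated spot-level tissue.

Simulates a four-layer tissue with two dominant cell types per layer,
aggregates single cells to ~290 spots, and fits the factor model with a
Gaussian-process prior over locations. The printed bandwidth (gamma) is the
kernel length-scale chosen from the expression data, tau is the estimated
strength of spatially structured signal relative to noise, and the kernel
rank is the truncation that keeps 90% of the kernel variance.
"""

from spatialpca import filter_matrix, normalize_and_standardize
from spatialpca.pipeline import fit_spatial_pcs, simulate_spot_dataset

counts, coords, truth = simulate_spot_dataset(seed=1, scenario="S2")
counts = filter_matrix(counts, 20, 20)
expr = normalize_and_standardize(counts)
fit, scaled = fit_spatial_pcs(expr, coords, d=20)

print(f"spots: {expr.n_locations}, genes: {expr.n_genes}")
print(f"bandwidth gamma = {fit.kernel.gamma:.4f} (scaled-coordinate units)")
print(f"kernel rank r = {fit.kernel.rank} of {fit.kernel.n}")
print(f"tau = {fit.tau:.2f}  sigma0^2 = {fit.sigma0_sq:.4f}")
print(f"marginal log-likelihood = {fit.loglik:.1f}")
print(f"spatial PCs: {fit.Z.shape[0]} factors x {fit.Z.shape[1]} locations")
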