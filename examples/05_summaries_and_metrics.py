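"""RGB embedding summary, trajectory arrows, and evaluation metrics.

Summarizes fitted factors into three RGB channels with the variance-weighted
scalar statistic, builds a trajectory arrow grid from a synthetic pseudo-time
that increases across the layers, and reports the standard evaluation
metrics of a detected labeling against the truth.
"""

import numpy as np

from spatialpca import cluster_pcs, filter_matrix, normalize_and_standardize
from spatialpca.metrics import ari, chaos, lisi, morans_i, nmi, pas, pseudo_r2_mcfadden
from spatialpca.pipeline import fit_spatial_pcs, simulate_spot_dataset
from spatialpca.summaries import rgb_summary, trajectory_arrows

counts, coords, truth = simulate_spot_dataset(seed=3, scenario="S2")
counts = filter_matrix(counts, 20, 20)
keep = np.array([int(s[4:]) for s in counts.location_ids])
coords, truth = coords[keep], truth[keep]
expr = normalize_and_standardize(counts)
fit, scaled = fit_spatial_pcs(expr, coords, d=20)

labels = cluster_pcs(fit.Z, target_clusters=4, seed=3).labels
print(f"ARI {ari(truth, labels):.3f}  NMI {nmi(truth, labels):.3f}")
print(f"CHAOS {chaos(labels, scaled):.3f}  PAS {pas(labels, scaled):.3f}  "
      f"median LISI {np.nanmedian(lisi(labels, scaled, perplexity=15)):.3f}")
print(f"pseudo-R2 of spatial PCs for true layers: "
      f"{pseudo_r2_mcfadden(fit.Z.T, truth):.3f}")
print(f"Moran's I of spatial PC 1: {morans_i(fit.Z[0], scaled):.3f}")

summary = rgb_summary(fit.Z, embed="first3", coords=scaled)
print(f"RGB weighted statistic: mean {summary.weighted.mean():+.2f}, "
      f"median neighborhood variance {np.median(summary.neighborhood_variance):.4f}")

pseudotime = scaled.coords[:, 1]  # progression across the layers
# coarse grid candidates suit this ~290-spot tissue (the default 10..30
# candidates target datasets with thousands of locations)
arrows, grid = trajectory_arrows(pseudotime, labels, scaled, grid_candidates=(4, 6, 8))
print(f"trajectory: {arrows.shape[0]} arrows on a {grid}x{grid} grid")
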