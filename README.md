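# spatialpca

Spatially aware probabilistic PCA for spatial transcriptomics.

Spatial transcriptomics measures genome-wide expression at tissue locations
with known coordinates. Ordinary dimension reduction (PCA, NMF) ignores those
coordinates, yet neighboring locations share cell-type composition and
expression — so their low-dimensional representations should be similar too.
This package infers **spatial PCs**: latent factors with a Gaussian-process
prior over tissue locations, which preserve spatial correlation in the
low-dimensional space and markedly improve downstream spatial-domain
detection, high-resolution map reconstruction, and tissue trajectory
visualization. It is written for computational biologists analyzing
spot-level (Visium/ST), bead-level (Slide-seq) or single-cell-resolution
spatial data from Python.

## Model

For a standardized gene × location matrix **Y** (m × n) the factor model is

```
Y = (X B)ᵀ + W Z + E,          E_ji ~ N(0, σ₀²)
Z_l· ~ MVN(0, σ₀² τ K),         l = 1..d
K(s_i, s_j) = exp(−‖s_i − s_j‖² / γ)
```

with `X` covariates (intercept only by default), `W` an m × d orthonormal
loading matrix, and `Z` the d × n spatial PCs. The kernel bandwidth γ is the
median per-gene bandwidth of the expression values (Silverman's rule of
thumb for n > 5000, the Sheather–Jones plug-in otherwise), computed on
coordinates scaled to unit variance per axis. `B` and `Z` are integrated out
analytically; `(W, τ, σ₀²)` maximize the marginal likelihood via a truncated
kernel eigendecomposition (rank chosen to keep ≥ 90% of kernel variance),
and the spatial PCs are the posterior mean `E[Z | Y]`. Factors at new,
unmeasured locations follow by Gaussian-process conditioning,
`Z̃ = K(s̃,s) K(s,s)⁻¹ Z`, with predicted expression `Ỹ = W Z̃`.

Around the core model the package provides: spatial-domain detection
(SNN graph + Walktrap, or KNN + Louvain, with silhouette-based cluster-number
selection and majority-vote spatial refinement), subspot geometries for
high-resolution maps (9 per square-array spot, 6 per hexagonal, 4 generic),
evaluation metrics (ARI, NMI, CHAOS, PAS, LISI, McFadden-adjusted pseudo-R²,
metagene enrichment, Moran's I), RGB/trajectory visualization summaries, and
a synthetic-tissue simulator (layered geometries, per-layer multinomial
cell-type scenarios, gamma–Poisson counts, spot aggregation, cell splitting).

## Worked example

```bash
python examples/02_domain_detection.py
```

simulates a four-layer cortical tissue (2,000 cells, 1,000 genes, two
dominant cell types per layer) aggregated to 289 spots, fits 20 spatial PCs,
and runs the identical Walktrap clustering on the spatial PCs and on
ordinary PCA scores of the same matrix:

```
spots: 289   estimated tau: 25.4
ARI   spatial PCs: 0.908   PCA: 0.484
CHAOS spatial PCs: 0.204   PCA: 0.230
PAS   spatial PCs: 0.014   PCA: 0.287
```

ARI measures agreement with the true layers (1 = perfect); the spatial prior
nearly doubles it here. CHAOS (mean within-domain nearest-neighbor edge
length) and PAS (fraction of spots disagreeing with ≥ 6 of 10 spatial
neighbors) are lower for the spatial PCs: the detected domains are spatially
smoother. The other scripts in `examples/` walk through fitting,
high-resolution imputation, the tissue simulator, and the summary
statistics, each printing the numbers it computes.

A thin CLI mirrors the same stages
(`spatialpca fit|impute|cluster|metrics|simulate|summarize`, see
`spatialpca --help`); the importable API is the primary interface.

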