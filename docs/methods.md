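# Methods

## The model and its inference

The generative model treats the standardized expression matrix `Y` (genes ×
locations) as a low-rank signal plus noise, `Y = (XB)ᵀ + WZ + E`, where the
d factor time-courses over space, the rows of `Z`, carry a Gaussian-process
prior `Z_l ~ MVN(0, σ₀²τK)` with Gaussian kernel
`K(s,s') = exp(−‖s−s'‖²/γ)`. The model assumes (i) expression has been
normalized and gene-standardized, so a homoscedastic Gaussian error is
tolerable; (ii) spatial correlation is stationary and isotropic on the
scaled coordinates, shared by all factors (a single τ and γ); (iii) the
loading matrix is orthonormal, which resolves rotational non-identifiability
exactly as in probabilistic PCA.

Inference integrates out the covariate coefficients `B` (equivalently:
projects the data columns onto the orthogonal complement of `X`; for the
default intercept-only `X` this is per-gene centering) and the factors `Z`.
In the kernel eigenbasis `K = U Λ Uᵀ` the marginal covariance diagonalizes:
each (factor, eigen-direction k) pair is Gaussian with variance
`σ₀²(1 + τλ_k)` and every other direction has variance `σ₀²`. Hence

* the optimal `W` for fixed τ spans the top-d left singular space of
  `(Y U) diag(√w_k)` with `w_k = τλ_k/(1+τλ_k)`;
* `σ₀²` profiles in closed form (residual sum of squares over `mn`; the
  REML-style degrees-of-freedom correction for the projected-out covariates
  is deliberately omitted — for q = 1 it is negligible and no correction is
  canonical here);
* τ reduces to a 1-D search: a 21-point log-spaced grid on `[1e−10, 1e10]`
  followed by golden-section refinement of the bracketing interval, ties
  broken toward smaller τ (the weaker prior). The fit is deterministic.

The posterior spatial PCs are `E[Z|Y] = U diag(w_k) Uᵀ (WᵀY)ᵀ` per factor —
the raw projections shrunk toward spatial smoothness. All three closed-form
expressions are validated in the test suite against dense multivariate-
normal oracles built from the explicit `(mn)×(mn)` covariance.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `d` | number of spatial PCs | 20 | standard for downstream clustering |
| `gamma` | kernel length-scale, squared scaled-coordinate units | data-driven | median per-gene bandwidth: Silverman `0.9·min(σ̂, IQR/1.34)·n^(−1/5)` when n > 5000, Sheather–Jones solve-the-equation plug-in otherwise |
| `variance_threshold` | kernel spectrum kept | 0.90 | rank/accuracy tradeoff |
| `sparse_cutoff` | kernel entries zeroed below | 1e−20 | memory only; moves eigenvalues by ≤ n·cutoff |
| `knn_k` | neighbor count for SNN/KNN graphs | 10 | typical for hundreds–thousands of locations |
| `jitter` | kriging solve regularizer | 1e−8·mean(diag K) | conditioning of the kernel system |

Coordinates are always z-scored per axis before kernel construction. The
bandwidth is derived from the spread of standardized expression values yet
applied to spatial distances; putting both on a unit-variance scale is the
one convention that makes those units coherent, and it also makes γ
comparable across platforms with different physical units.

The Sheather–Jones estimator uses the classical two-stage pilot bandwidths
with Gaussian-kernel derivative functionals (diagonal terms included),
pairwise differences binned to 1000 bins so each fixed-point evaluation is
O(bins), and Brent root-finding on `[h₀/16, 16h₀]` around the normal-
reference start. Genes whose root search fails are skipped; the median over
genes is used. On Gaussian samples the result lands within a few percent of
the `1.059·σ·n^(−1/5)` optimum.

## Domain detection and refinement

Clustering operates purely in factor space: an SNN graph (weight
`|shared|/(2k−|shared|)`, zero-weight edges dropped) cut with the Walktrap
dendrogram at the requested cluster count, or an unweighted symmetric KNN
graph under Louvain with the resolution bisected on `[0.01, 5]` (at most 50
attempts) until the count matches. Cluster-number selection maximizes the
mean silhouette width on factor-space distances, ties toward fewer
clusters. Refinement is a single simultaneous pass: each spot adopts the
strict-majority label of itself plus its `neighbor_count` spatially nearest
spots (4 suits square arrays, 6 hexagonal); votes always reference the
pre-pass labeling, so the result is order-independent, and iteration to a
fixed point is intentionally not performed — one pass removes isolated
speckle without eroding thin genuine structures.

## Evaluation metrics

CHAOS connects each spot to its nearest same-cluster spot and averages the
edge lengths over all spots; PAS counts spots disagreeing with ≥ 6 of their
10 nearest neighbors; both use scaled coordinates so they are comparable
across datasets. LISI calibrates Gaussian weights over the 3·perplexity
nearest spots until the weight entropy equals log(perplexity) (bisection,
1e−5) and reports the inverse Simpson index `1/Σp(k)²` of the label
probabilities — the effective number of labels locally; the squared form is
used since the unsquared sum is identically one. The McFadden-adjusted
pseudo-R² fits a ridge-stabilized multinomial regression of the true
domains on the components and subtracts one likelihood unit per estimated
non-intercept parameter, `p(C−1)`. Metagene enrichment finds per-domain
up-regulated genes by one-vs-rest rank-sum tests (Benjamini–Hochberg within
each comparison, adjusted p < 0.001, positive fold change) — a
distribution-free stand-in for hurdle-model differential expression at
identical thresholds — averages them into a min–max-scaled metagene, matches
each true domain to the detected domain with the largest overlap fraction
(≥ 35% of the detected domain's spots), and reports the inside/outside mean
ratio.

## The synthetic-tissue generator

The generator emulates a layered cortex: four equal-area parallel bands (or
six stripes alternating between two domains) on a pixel lattice, cells
sampled uniformly without replacement, per-layer multinomial cell-type
draws with the dominance order rotating one position per layer, and
scenario tables 70/10/10/10, 45/45/5/5, 60/30/5/5, 35/30/30/5 (stripes:
60/40, 60/30/5/5, 60/20/20). Counts follow a gamma–Poisson scheme: gene
base means `Gamma(shape 0.6, rate 0.3)`, per-group multiplicative DE
factors `LogNormal(0.1, 0.4)` (reciprocal with probability ½) on a
`de_prob = 0.5` fraction of genes, library sizes `LogNormal(11, 0.2)`,
Poisson sampling from the normalized group profiles. Aggregation bins cells
into square subspots merged 3×3 into spots (spot coordinate = central
subspot; majority truth labels retained at both levels), and the cell-split
variant removes a random quarter of cells, dividing each one's counts among
its four nearest surviving cells with uniform-Dirichlet weights via
per-gene multinomial draws — totals are conserved exactly and counts stay
integral.

What the generator does *not* emulate: real tissues have curved,
unequal-area layers, platform-specific capture efficiency and zero
inflation, segmentation noise, and empirically estimated (not stylized)
splat parameters. Passing tests therefore show that the method recovers
*this* class of layered, multinomially mixed, gamma–Poisson tissues — the
directional claim that the spatial prior beats ordinary PCA for domain
detection — not that any particular published accuracy value is reproduced.
An `attach_counts`-compatible hook accepts user-supplied counts for
empirically calibrated simulations.

## Problem sizes used in the checks

The end-to-end comparison runs at 2,000 cells × 1,000 genes aggregated to
~289 spots with 5 seeds, and parameter recovery at m=100 genes × n=400
locations — sizes chosen so the full pipeline (bandwidth selection, kernel
eigendecomposition, τ search, clustering, metrics) exercises every code
path while a complete run stays in the tens of seconds on a laptop core.
Exact-oracle checks use m ≤ 6, n ≤ 10 where the dense `(mn)×(mn)`
covariance is tractable.

## Numerical choices and degenerate inputs

Negative kernel eigenvalues (jitter from sparsification or near-duplicate
locations) are clipped to zero before the variance fraction is computed.
Loading signs follow the largest-magnitude-entry-positive convention. When
the fitted τ is numerically zero the loadings fall back to the PCA basis of
the projected data so they remain well defined. Zero-variance genes and
zero-count locations are dropped with warnings; constant coordinate axes,
all-singleton clusterings, and constant inputs to Moran's I are errors.
Subspots outside the convex hull of the measured locations are dropped
(hull boundary kept): the conditional mean interpolates, it does not
extrapolate. The six-subspot hexagonal offsets (two columns of three at
±¼ / ±⅓ of the nearest-neighbor spacing) are a fixed documented table;
platforms fix the count, not the offsets.

## Known limitations

* The Gaussian likelihood on standardized values ignores the count
  mean–variance relationship; a Poisson/negative-binomial observation model
  is out of scope.
* A single τ is shared across factors; factors with genuinely different
  spatial scales are averaged.
* Maximum-likelihood fitting picks up chance alignment on pure-noise data
  (finite-sample spiked-covariance effect), so τ̂ under the null is small
  but not zero — at m=100, n=400 it sits well below 1 yet clearly above
  machine zero. Likewise, subspace recovery at m=100, n=400, τ=10 operates
  near the statistical information limit (~10° largest principal angle for
  d=3); no estimator of this model does materially better at that size.
* Pseudo-time is consumed, never inferred; trajectory arrows visualize an
  externally supplied ordering.
* Multi-sample analysis assumes pre-integrated expression; the block
  kernel only encodes a-priori independence between sections.
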