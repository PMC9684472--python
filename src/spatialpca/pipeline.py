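"""End-to-end convenience pipelines.

These wire the modules together for the common workflow: simulate (or load)
a spot-level dataset, preprocess, build the kernel, fit the spatially aware
factor model, cluster the factors into domains, and score the result. The
same clustering is applied to ordinary PCA scores of the identical input so
the spatial and non-spatial routes can be compared like for like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import domains, kernels, metrics, model, simulate
from .io import ExpressionMatrix, filter_matrix, normalize_and_standardize

__all__ = [
    "simulate_spot_dataset",
    "ordinary_pca_scores",
    "fit_spatial_pcs",
    "domain_detection_comparison",
]


def simulate_spot_dataset(
    seed: int = 0,
    scenario: str = "S2",
    layout: str = "bands4",
    n_cells: int = 2000,
    n_genes: int = 1000,
    lattice: tuple[int, int] = (102, 102),
    grid_edge: float = 2.0,
    n_split: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Layered tissue aggregated to spots.

    Returns ``(counts, spot_coords, spot_labels)`` with counts genes x spots.
    The defaults give roughly 290 occupied spots of ~7 cells each.
    """
    tissue = simulate.make_layered_tissue(
        n_cells, lattice=lattice, layout=layout, seed=seed
    )
    tissue = simulate.assign_cell_types(tissue, scenario=scenario, seed=seed + 1)
    tissue = simulate.attach_counts(tissue, n_genes=n_genes, seed=seed + 2)
    if n_split:
        tissue = simulate.cell_split(tissue, n_split=n_split, seed=seed + 3)
    tissue = simulate.aggregate_to_spots(tissue, grid_edge=grid_edge)
    n_spots = tissue.spot_coords.shape[0]
    expr = ExpressionMatrix(
        tissue.spot_counts,
        gene_ids=[f"gene{j}" for j in range(n_genes)],
        location_ids=[f"spot{i}" for i in range(n_spots)],
        state="counts",
    )
    return expr, tissue.spot_coords, tissue.spot_labels


def ordinary_pca_scores(expr: ExpressionMatrix, d: int) -> np.ndarray:
    """Top-d principal-component scores (d x n) of standardized expression."""
    Y = model.project_covariates(
        expr.values, model.CovariateTable.intercept_only(expr.n_locations)
    )
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    return (s[:d, None] * Vt[:d])


def fit_spatial_pcs(
    expr: ExpressionMatrix,
    raw_coords: np.ndarray,
    d: int = 20,
    bandwidth: str | float = "auto",
    variance_threshold: float = kernels.DEFAULT_VARIANCE_THRESHOLD,
) -> tuple[model.SpatialPCAFit, kernels.SpatialCoordinates]:
    """Standardized expression -> kernel -> fitted spatial factors."""
    if expr.state != "standardized":
        expr = normalize_and_standardize(expr)
    coords = kernels.scale_coordinates(kernels.SpatialCoordinates(raw_coords))
    if isinstance(bandwidth, str):
        gamma = kernels.select_bandwidth(expr, method=bandwidth)
    else:
        gamma = float(bandwidth)
    kern = kernels.build_kernel(coords, gamma)
    kern = kernels.lowrank_eigen(kern, variance_threshold)
    fitted = model.fit(expr, kern, d=d)
    return fitted, coords


@dataclass
class ComparisonResult:
    ari_spatial: float
    ari_pca: float
    chaos_spatial: float
    chaos_pca: float
    pas_spatial: float
    pas_pca: float
    tau: float
    gamma: float
    n_spots: int


def domain_detection_comparison(
    seed: int = 0,
    scenario: str = "S2",
    layout: str = "bands4",
    n_cells: int = 2000,
    n_genes: int = 1000,
    d: int = 20,
    target_clusters: int = 4,
    **dataset_kwargs,
) -> ComparisonResult:
    """Spatial factor model vs ordinary PCA on one simulated tissue.

    Both routes standardize the same filtered counts, reduce to ``d``
    components and run the identical Walktrap clustering into
    ``target_clusters`` domains; accuracy is the ARI against the true layer
    labels, smoothness is CHAOS/PAS on the scaled spot coordinates.
    """
    counts, spot_coords, truth = simulate_spot_dataset(
        seed=seed, scenario=scenario, layout=layout,
        n_cells=n_cells, n_genes=n_genes, **dataset_kwargs,
    )
    counts = filter_matrix(counts, 20, 20)
    keep = np.array([int(s[4:]) for s in counts.location_ids])
    spot_coords, truth = spot_coords[keep], truth[keep]
    expr = normalize_and_standardize(counts)
    fitted, coords = fit_spatial_pcs(expr, spot_coords, d=d)
    z_spatial = fitted.Z
    z_pca = ordinary_pca_scores(expr, d)
    lab_spatial = domains.cluster_pcs(
        z_spatial, method="walktrap_snn", target_clusters=target_clusters, seed=seed
    ).labels
    lab_pca = domains.cluster_pcs(
        z_pca, method="walktrap_snn", target_clusters=target_clusters, seed=seed
    ).labels
    return ComparisonResult(
        ari_spatial=metrics.ari(truth, lab_spatial),
        ari_pca=metrics.ari(truth, lab_pca),
        chaos_spatial=metrics.chaos(lab_spatial, coords),
        chaos_pca=metrics.chaos(lab_pca, coords),
        pas_spatial=metrics.pas(lab_spatial, coords),
        pas_pca=metrics.pas(lab_pca, coords),
        tau=fitted.tau,
        gamma=fitted.kernel.gamma,
        n_spots=expr.n_locations,
    )
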