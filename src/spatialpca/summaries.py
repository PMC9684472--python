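"""Visualization-ready summaries of the spatial factors.

``rgb_summary`` compresses the factors into three components (the first
three factors, or a 3-D UMAP/t-SNE embedding), min-max scales each to
[0, 1] as red/green/blue channels, and derives the variance-weighted scalar

    RGB_weighted = (R var(R) + G var(G) + B var(B)) / (var(R) + var(G) + var(B)),

standardized across locations, together with its sample variance over each
spot and its six nearest neighbors (small values indicate locally smooth
embeddings).

``trajectory_arrows`` overlays an evenly spaced square grid on the tissue
and, inside each occupied cell, draws an arrow from the location with the
smallest pseudo-time to the one with the largest; the grid size is the
smallest candidate for which at least a third of the arrows cross a domain
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .domains import DomainLabeling
from .kernels import SpatialCoordinates

__all__ = ["RgbSummary", "rgb_summary", "trajectory_arrows"]

DEFAULT_GRID_CANDIDATES = (10, 15, 20, 25, 30)
MIN_CROSS_FRACTION = 1.0 / 3.0


@dataclass
class RgbSummary:
    rgb: np.ndarray  # locations x 3, each channel in [0, 1]
    weighted: np.ndarray  # standardized weighted channel value
    neighborhood_variance: np.ndarray


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi <= lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def rgb_summary(
    Z: np.ndarray,
    embed: Literal["first3", "umap3", "tsne3"] = "first3",
    coords: SpatialCoordinates | np.ndarray | None = None,
    seed: int = 0,
) -> RgbSummary:
    """Three-channel RGB summary of a d x n factor matrix (d >= 3)."""
    Z = np.asarray(Z, float)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 factors for an RGB summary")
    if embed == "first3":
        comps = Z[:3].T
    elif embed == "umap3":
        import umap

        comps = umap.UMAP(n_components=3, random_state=seed).fit_transform(Z.T)
    elif embed == "tsne3":
        from sklearn.manifold import TSNE

        comps = TSNE(n_components=3, random_state=seed, init="pca").fit_transform(Z.T)
    else:
        raise ValueError(f"unknown embedding {embed!r}")
    rgb = np.column_stack([_minmax(comps[:, j]) for j in range(3)])
    variances = rgb.var(axis=0, ddof=1)
    total = variances.sum()
    if total <= 0:
        weighted_raw = rgb.mean(axis=1)
    else:
        weighted_raw = rgb @ variances / total
    sd = weighted_raw.std(ddof=1)
    weighted = (weighted_raw - weighted_raw.mean()) / (sd if sd > 0 else 1.0)
    neigh_var = np.full(rgb.shape[0], np.nan)
    if coords is not None:
        pts = coords.coords if isinstance(coords, SpatialCoordinates) else np.asarray(coords)
        k = min(6, pts.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, idx = nn.kneighbors(pts)
        neigh_var = np.array([np.var(weighted[row], ddof=1) for row in idx])
    return RgbSummary(rgb=rgb, weighted=weighted, neighborhood_variance=neigh_var)


def trajectory_arrows(
    pseudotime: Sequence[float],
    labels: DomainLabeling | np.ndarray,
    coords: SpatialCoordinates | np.ndarray,
    grid_candidates: Sequence[int] = DEFAULT_GRID_CANDIDATES,
) -> tuple[np.ndarray, int]:
    """Arrow list ``(x0, y0, x1, y1)`` per occupied grid cell + chosen size.

    Arrows run from the minimum- to the maximum-pseudo-time location within
    each cell of a ``g x g`` grid over the coordinate bounding box; ``g`` is
    the smallest candidate for which at least 1/3 of the arrows cross a
    domain boundary, falling back to the largest candidate with a warning.
    """
    t = np.asarray(pseudotime, float)
    lab = labels.labels if isinstance(labels, DomainLabeling) else np.asarray(labels)
    pts = coords.coords if isinstance(coords, SpatialCoordinates) else np.asarray(coords)
    pts = pts[:, :2]
    if np.allclose(t, t[0]):
        warnings.warn("constant pseudo-time: no arrows", stacklevel=2)
        return np.empty((0, 4)), max(grid_candidates)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0

    def arrows_for(g: int) -> tuple[np.ndarray, float]:
        cell = np.minimum((((pts - lo) / span) * g).astype(int), g - 1)
        cell_id = cell[:, 0] * g + cell[:, 1]
        rows, crossings = [], 0
        for c in np.unique(cell_id):
            members = np.where(cell_id == c)[0]
            if members.size < 2:
                continue
            tc = t[members]
            if np.allclose(tc, tc[0]):
                continue
            start = members[np.argmin(tc)]
            end = members[np.argmax(tc)]
            rows.append((*pts[start], *pts[end]))
            crossings += int(lab[start] != lab[end])
        arr = np.asarray(rows) if rows else np.empty((0, 4))
        frac = crossings / len(rows) if rows else 0.0
        return arr, frac

    for g in sorted(grid_candidates):
        arr, frac = arrows_for(g)
        if arr.shape[0] and frac >= MIN_CROSS_FRACTION:
            return arr, g
    g = max(grid_candidates)
    warnings.warn(
        "no grid size reached the 1/3 cross-domain arrow fraction; "
        f"using the largest candidate {g}",
        stacklevel=2,
    )
    return arrows_for(g)[0], g
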