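"""Spatial covariance machinery.

The factor model places a Gaussian-process prior over tissue locations whose
covariance is ``K(s_i, s_j) = exp(-|s_i - s_j|^2 / gamma)``. This module
builds that kernel: it scales coordinates to unit variance per axis, picks
the bandwidth ``gamma`` from the expression data (Silverman's rule of thumb
for large samples, the Sheather-Jones solve-the-equation plug-in otherwise,
median across genes), supports a graph-distance kernel on the Delaunay
triangulation, truncates the kernel spectrum to a variance fraction, and
stitches per-sample kernels into a block-diagonal multi-sample kernel.

Coordinates are always scaled before kernel construction: the bandwidth is
derived from the spread of (standardized) expression values, so spatial
distances are put on the same unit-variance scale to keep the two coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.spatial import Delaunay, distance
from scipy.sparse.csgraph import shortest_path
from scipy import sparse

from .io import ExpressionMatrix

__all__ = [
    "SpatialCoordinates",
    "SpatialKernel",
    "scale_coordinates",
    "inverse_scale",
    "silverman_bandwidth",
    "sheather_jones_bandwidth",
    "select_bandwidth",
    "build_kernel",
    "delaunay_distance_matrix",
    "lowrank_eigen",
    "block_kernel",
]

KernelKind = Literal["gaussian", "delaunay", "custom", "block"]

#: default sparsity cutoff: kernel entries below this are zeroed
DEFAULT_SPARSE_CUTOFF = 1e-20
#: default retained variance fraction for the truncated eigendecomposition
DEFAULT_VARIANCE_THRESHOLD = 0.90
#: sample-size switch between Sheather-Jones and Silverman bandwidths
LARGE_SAMPLE_N = 5000


@dataclass
class SpatialCoordinates:
    """Location x k coordinates (k in {2, 3}) with a scaling record."""

    coords: np.ndarray
    scaled: bool = False
    axis_means: np.ndarray | None = None
    axis_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("coordinates must be 2-D or 3-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class SpatialKernel:
    """Kernel matrix with its retained eigenpairs and provenance."""

    K: np.ndarray
    coords: SpatialCoordinates
    gamma: float
    kind: KernelKind = "gaussian"
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None
    variance_fraction: float | None = None

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def rank(self) -> int | None:
        return None if self.eigvals is None else len(self.eigvals)


def scale_coordinates(coords: SpatialCoordinates) -> SpatialCoordinates:
    """Center each axis and scale it to unit sample SD."""
    if coords.scaled:
        return coords
    means = coords.coords.mean(axis=0)
    sds = coords.coords.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("constant coordinate axis: degenerate geometry")
    return SpatialCoordinates(
        (coords.coords - means) / sds, scaled=True, axis_means=means, axis_sds=sds
    )


def inverse_scale(coords: SpatialCoordinates) -> np.ndarray:
    """Map scaled coordinates back to the original units."""
    if not coords.scaled:
        return coords.coords.copy()
    if coords.axis_means is None or coords.axis_sds is None:
        raise ValueError("scaling record missing; cannot invert")
    return coords.coords * coords.axis_sds + coords.axis_means


# ---------------------------------------------------------------------------
# bandwidth selection


def silverman_bandwidth(x: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5) on one expression vector."""
    x = np.asarray(x, float)
    n = x.size
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        return float("nan")
    return 0.9 * spread * n ** (-1 / 5)


def _phi4(u: np.ndarray) -> np.ndarray:
    return (u**4 - 6 * u**2 + 3) * np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)


def _phi6(u: np.ndarray) -> np.ndarray:
    return (
        (u**6 - 15 * u**4 + 45 * u**2 - 15)
        * np.exp(-0.5 * u**2)
        / np.sqrt(2 * np.pi)
    )


def sheather_jones_bandwidth(x: np.ndarray, n_bins: int = 1000) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth.

    Uses the classical two-stage pilot estimates of the integrated squared
    density derivatives (Gaussian kernel, diagonal terms included) and solves
    the fixed-point equation with Brent's method. Pairwise differences are
    binned once so each evaluation of the equation is O(n_bins). Returns NaN
    when the input is degenerate or the root search fails.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 4:
        return float("nan")
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    lam = min(sd, (q75 - q25) / 1.349)
    if lam <= 0:
        return float("nan")
    # histogram of pairwise absolute differences (i < j), one pass
    absdiff = np.abs(x[:, None] - x[None, :])[np.triu_indices(n, k=1)]
    span = absdiff.max()
    if span <= 0:
        return float("nan")
    delta = span / (n_bins - 1)
    cnt = np.bincount(np.rint(absdiff / delta).astype(int), minlength=n_bins)
    grid = np.arange(n_bins) * delta

    def sd_hat(h: float) -> float:
        # estimate of the integrated squared second derivative of the density
        s = 2.0 * np.dot(cnt, _phi4(grid / h)) + n * _phi4(np.zeros(1))[0]
        return float(s / (n * (n - 1) * h**5))

    def td_hat(h: float) -> float:
        s = 2.0 * np.dot(cnt, _phi6(grid / h)) + n * _phi6(np.zeros(1))[0]
        return float(-s / (n * (n - 1) * h**7))

    a = 0.920 * lam * n ** (-1 / 7)
    b = 0.912 * lam * n ** (-1 / 9)
    sda, tdb = sd_hat(a), td_hat(b)
    if not (np.isfinite(sda) and np.isfinite(tdb)) or sda <= 0 or tdb <= 0:
        return float("nan")
    rk = 1.0 / (2.0 * np.sqrt(np.pi))  # roughness of the Gaussian kernel

    def equation(h: float) -> float:
        alpha2 = 1.357 * (sda / tdb) ** (1 / 7) * h ** (5 / 7)
        s = sd_hat(alpha2)
        if s <= 0:
            return np.inf
        return (rk / (n * s)) ** (1 / 5) - h

    h0 = 1.06 * lam * n ** (-1 / 5)
    lo, hi = h0 / 16, h0 * 16
    try:
        flo, fhi = equation(lo), equation(hi)
        if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
            return float("nan")
        return float(optimize.brentq(equation, lo, hi, xtol=1e-8))
    except (ValueError, RuntimeError):
        return float("nan")


def select_bandwidth(
    expr: ExpressionMatrix,
    n: int | None = None,
    method: Literal["auto", "silverman", "sheather_jones"] = "auto",
) -> float:
    """Median per-gene bandwidth of the standardized expression vectors.

    ``auto`` uses Silverman's rule of thumb for large samples (n > 5000) and
    the Sheather-Jones plug-in otherwise. Genes with degenerate bandwidths
    are skipped.
    """
    if expr.state != "standardized":
        raise ValueError("bandwidth selection expects standardized expression")
    if n is None:
        n = expr.n_locations
    if method == "auto":
        method = "silverman" if n > LARGE_SAMPLE_N else "sheather_jones"
    estimator = (
        silverman_bandwidth if method == "silverman" else sheather_jones_bandwidth
    )
    bandwidths = np.array([estimator(row) for row in expr.values])
    bandwidths = bandwidths[np.isfinite(bandwidths) & (bandwidths > 0)]
    if bandwidths.size == 0:
        raise ValueError("no gene yielded a finite positive bandwidth")
    return float(np.median(bandwidths))


# ---------------------------------------------------------------------------
# kernel construction


def build_kernel(
    coords: SpatialCoordinates,
    gamma: float,
    sparse_cutoff: float = DEFAULT_SPARSE_CUTOFF,
    histology: np.ndarray | None = None,
) -> SpatialKernel:
    """Gaussian kernel ``exp(-d^2/gamma)`` on scaled coordinates.

    ``histology`` columns, when given, are z-scored and concatenated as
    pseudo-dimensions of the distance. Entries below ``sparse_cutoff`` are
    zeroed; the diagonal is exactly one.
    """
    if not coords.scaled:
        raise ValueError("scale coordinates before building the kernel")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    feats = coords.coords
    if histology is not None:
        histology = np.atleast_2d(np.asarray(histology, float))
        if histology.shape[0] != coords.n:
            raise ValueError("histology rows must match location count")
        sds = histology.std(axis=0, ddof=1)
        if np.any(sds <= 0):
            raise ValueError("constant histology pseudo-dimension")
        feats = np.hstack([feats, (histology - histology.mean(axis=0)) / sds])
    d2 = distance.squareform(distance.pdist(feats, "sqeuclidean"))
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite distance between locations")
    K = np.exp(-d2 / gamma)
    K[K < sparse_cutoff] = 0.0
    np.fill_diagonal(K, 1.0)
    return SpatialKernel(K=K, coords=coords, gamma=gamma, kind="gaussian")


def delaunay_distance_matrix(coords: SpatialCoordinates) -> np.ndarray:
    """Hop-count distances on the Delaunay triangulation graph.

    Two locations are neighbors when their Voronoi cells share an edge, i.e.
    when they are joined by a Delaunay edge; the distance is the minimum
    number of edges on a path between them.
    """
    if coords.k != 2:
        raise ValueError("Delaunay distance requires 2-D coordinates")
    pts = coords.coords
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 locations")
    tri = Delaunay(pts)
    n = pts.shape[0]
    rows, cols = [], []
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            rows.append(a)
            cols.append(b)
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).maximum(
        sparse.coo_matrix((np.ones(len(rows)), (cols, rows)), shape=(n, n))
    )
    hops = shortest_path(adj.tocsr(), method="D", unweighted=True, directed=False)
    if np.isinf(hops).any():
        raise ValueError("Delaunay graph is disconnected")
    return hops.astype(int)


def delaunay_kernel(
    coords: SpatialCoordinates,
    gamma: float,
    sparse_cutoff: float = DEFAULT_SPARSE_CUTOFF,
) -> SpatialKernel:
    """Gaussian-form kernel with squared Delaunay hop distance."""
    hops = delaunay_distance_matrix(coords)
    K = np.exp(-(hops.astype(float) ** 2) / gamma)
    K[K < sparse_cutoff] = 0.0
    np.fill_diagonal(K, 1.0)
    return SpatialKernel(K=K, coords=coords, gamma=gamma, kind="delaunay")


def lowrank_eigen(
    kernel: SpatialKernel,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> SpatialKernel:
    """Retain the smallest leading eigenpair set capturing the threshold.

    Negative eigenvalues (numerical jitter) are clipped to zero before the
    cumulative variance fraction is computed.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    try:
        vals, vecs = linalg.eigh(kernel.K)
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"kernel eigendecomposition failed: {exc}") from exc
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    total = vals.sum()
    if total <= 0:
        raise ValueError("kernel has no positive spectrum")
    frac = np.cumsum(vals) / total
    r = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    return replace(
        kernel,
        eigvals=vals[:r],
        eigvecs=vecs[:, :r],
        variance_fraction=float(frac[r - 1]),
    )


def block_kernel(per_sample: Sequence[SpatialKernel]) -> SpatialKernel:
    """Block-diagonal kernel over concatenated samples.

    Locations of different samples are a priori uncorrelated; the eigenpairs
    of the block matrix are the union of the per-block eigenpairs re-sorted
    in descending order.
    """
    if len(per_sample) < 2:
        raise ValueError("block kernel needs at least 2 samples")
    for k in per_sample:
        if k.eigvals is None:
            raise ValueError("decompose each per-sample kernel first (lowrank_eigen)")
    sizes = [k.n for k in per_sample]
    n = sum(sizes)
    K = np.zeros((n, n))
    vals, vecs = [], []
    offset = 0
    for k, size in zip(per_sample, sizes):
        K[offset : offset + size, offset : offset + size] = k.K
        padded = np.zeros((n, k.eigvecs.shape[1]))
        padded[offset : offset + size] = k.eigvecs
        vals.append(k.eigvals)
        vecs.append(padded)
        offset += size
    vals = np.concatenate(vals)
    vecs = np.hstack(vecs)
    order = np.argsort(vals)[::-1]
    ks = [s.coords.k for s in per_sample]
    if len(set(ks)) != 1:
        raise ValueError("samples have mixed coordinate dimensionality")
    coords = SpatialCoordinates(
        np.vstack([s.coords.coords for s in per_sample]), scaled=True
    )
    frac = min(
        (k.variance_fraction for k in per_sample if k.variance_fraction is not None),
        default=None,
    )
    return SpatialKernel(
        K=K,
        coords=coords,
        gamma=float(np.mean([k.gamma for k in per_sample])),
        kind="block",
        eigvals=vals[order],
        eigvecs=vecs[:, order],
        variance_fraction=frac,
    )
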