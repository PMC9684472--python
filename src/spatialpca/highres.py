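"""High-resolution spatial map construction.

Because the factors carry a Gaussian-process prior, their values at new,
unmeasured locations have a closed-form conditional mean given the posterior
factors at the measured locations:

    Z_new = K(s_new, s) [K(s, s) + jitter I]^(-1) Z,

where the shared ``sigma0^2 * tau`` prefactor of the prior covariance
cancels. Predicted expression at the new locations is then ``W @ Z_new`` on
the standardized scale of the training data.

Subspot generators reproduce the common platform geometries: a 3x3 square
lattice per spot (9 subspots, square-array platforms), two offset columns of
three (6 subspots, hexagonal-array platforms), and a generic 4-corner split.
New locations outside the convex hull of the measured ones are dropped: the
model only interpolates where it is surrounded by observed expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import linalg
from scipy.spatial import Delaunay, cKDTree, distance

from .kernels import SpatialCoordinates
from .model import SpatialPCAFit

__all__ = [
    "NewLocations",
    "make_subspot_locations",
    "impute_spatial_pcs",
    "predict_expression",
]

Geometry = Literal["st9", "visium6", "generic4", "user"]

# subspot offset tables in units of the median nearest-neighbor distance.
# st9: centers of the 3x3 subcells of a spot-sized square.
_ST9_OFFSETS = np.array(
    [(dx, dy) for dy in (1 / 3, 0.0, -1 / 3) for dx in (-1 / 3, 0.0, 1 / 3)]
)
# visium6: two columns of three, splitting a hexagonal spot.
_VISIUM6_OFFSETS = np.array(
    [(dx, dy) for dx in (-1 / 4, 1 / 4) for dy in (-1 / 3, 0.0, 1 / 3)]
)
# generic4: corners of a square at +-1/4 of the nearest-neighbor distance.
_GENERIC4_OFFSETS = np.array([(-1 / 4, -1 / 4), (-1 / 4, 1 / 4), (1 / 4, -1 / 4), (1 / 4, 1 / 4)])

_OFFSET_TABLES = {
    "st9": _ST9_OFFSETS,
    "visium6": _VISIUM6_OFFSETS,
    "generic4": _GENERIC4_OFFSETS,
}


@dataclass
class NewLocations:
    """Unmeasured target locations with their source-spot parent map."""

    coords: np.ndarray
    parent: np.ndarray | None = None
    geometry: Geometry = "user"

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _median_nn_distance(pts: np.ndarray) -> float:
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(np.median(dists[:, 1]))


def make_subspot_locations(
    coords: SpatialCoordinates, geometry: Geometry = "generic4"
) -> NewLocations:
    """Place subspots around every measured spot.

    Offsets are proportional to the median nearest-neighbor spot distance.
    Subspots falling outside the convex hull of the measured locations are
    removed (boundary points are kept).
    """
    if not coords.scaled:
        raise ValueError("scale coordinates before constructing subspots")
    if coords.n < 2:
        raise ValueError("need at least 2 measured locations")
    if geometry not in _OFFSET_TABLES:
        raise ValueError(f"unknown geometry {geometry!r}")
    pts = coords.coords[:, :2]
    delta = _median_nn_distance(pts)
    offsets = _OFFSET_TABLES[geometry] * delta
    new = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    parent = np.repeat(np.arange(coords.n), len(offsets))
    if coords.n >= 3:
        hull = Delaunay(pts)
        inside = hull.find_simplex(new) >= 0
        n_drop = int((~inside).sum())
        if n_drop:
            warnings.warn(
                f"dropping {n_drop} subspot(s) outside the measured hull",
                stacklevel=2,
            )
        new, parent = new[inside], parent[inside]
    return NewLocations(coords=new, parent=parent, geometry=geometry)


def impute_spatial_pcs(
    fit: SpatialPCAFit, new: NewLocations, jitter: float | None = None
) -> np.ndarray:
    """Conditional-mean (kriging) imputation of the spatial PCs.

    ``jitter`` stabilizes the linear solve; the default is
    ``1e-8 * mean(diag K)``. With jitter 0 and a full-rank kernel, imputing
    at the measured locations returns the fitted factors exactly.
    """
    kernel = fit.kernel
    if kernel.kind not in ("gaussian", "custom"):
        raise ValueError(
            f"kernel kind {kernel.kind!r} cannot be evaluated at new coordinates"
        )
    if jitter is None:
        jitter = 1e-8 * float(np.mean(np.diag(kernel.K)))
    d2 = distance.cdist(
        new.coords, kernel.coords.coords[:, : new.coords.shape[1]], "sqeuclidean"
    )
    K_new = np.exp(-d2 / kernel.gamma)  # n_new x n
    A = kernel.K + jitter * np.eye(kernel.n)
    try:
        solved = linalg.solve(A, fit.Z.T, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "kernel system is singular; pass a positive jitter"
        ) from exc
    return (K_new @ solved).T


def predict_expression(
    fit: SpatialPCAFit,
    imputed: np.ndarray,
    genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Predicted expression ``W @ Z_new`` (standardized training scale)."""
    W = fit.W
    if genes is not None:
        index = {g: i for i, g in enumerate(fit.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in the fit: {missing}")
        W = W[[index[g] for g in genes]]
    if imputed.shape[0] != fit.d:
        raise ValueError("imputed factor matrix must have d rows")
    return W @ imputed
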