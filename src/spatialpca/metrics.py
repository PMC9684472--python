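"""Evaluation statistics for spatial clustering and embeddings.

Partition agreement uses the standard contingency-table ARI and NMI. The
spatial smoothness statistics follow the imaging literature:

* CHAOS — within each cluster connect every spot to its nearest same-cluster
  spot (one directed edge per spot) and average the Euclidean edge lengths
  over all spots; lower means spatially smoother domains.
* PAS — fraction of spots whose label differs from at least ``threshold``
  (default 6) of their ``k`` (default 10) nearest neighbors.
* LISI — per spot, the effective number of labels (inverse Simpson index of
  label probabilities) in a perplexity-calibrated Gaussian neighborhood.

Predictiveness of a low-dimensional embedding for known domains is measured
with the McFadden-adjusted pseudo-R^2 from a multinomial logistic
regression, and spatial autocorrelation of a single component with Moran's I
under row-normalized k-nearest-neighbor weights.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .kernels import SpatialCoordinates

__all__ = [
    "ari",
    "nmi",
    "chaos",
    "pas",
    "lisi",
    "pseudo_r2_mcfadden",
    "metagene_enrichment",
    "morans_i",
]


def _check_lengths(a: Sequence, b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return a, b


def ari(a: Sequence, b: Sequence) -> float:
    """Adjusted Rand index between two labelings."""
    a, b = _check_lengths(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a: Sequence, b: Sequence) -> float:
    """Normalized mutual information between two labelings."""
    a, b = _check_lengths(a, b)
    return float(normalized_mutual_info_score(a, b))


def _as_points(coords: SpatialCoordinates | np.ndarray) -> np.ndarray:
    if isinstance(coords, SpatialCoordinates):
        return coords.coords
    return np.atleast_2d(np.asarray(coords, float))


def chaos(labels: Sequence, coords: SpatialCoordinates | np.ndarray) -> float:
    """Mean within-cluster 1-nearest-neighbor edge length."""
    labels = np.asarray(labels)
    pts = _as_points(coords)
    total = 0.0
    any_edge = False
    for lab in np.unique(labels):
        members = pts[labels == lab]
        if members.shape[0] < 2:
            continue  # singleton clusters contribute no edge
        any_edge = True
        nn = NearestNeighbors(n_neighbors=2).fit(members)
        dists, _ = nn.kneighbors(members)
        total += float(dists[:, 1].sum())
    if not any_edge:
        raise ValueError("every cluster is a singleton; CHAOS undefined")
    return total / labels.size


def pas(
    labels: Sequence,
    coords: SpatialCoordinates | np.ndarray,
    k: int = 10,
    threshold: int = 6,
) -> float:
    """Proportion of abnormal spots (label disagrees with >= threshold of k NN)."""
    labels = np.asarray(labels)
    pts = _as_points(coords)
    n = labels.size
    if n <= k:
        raise ValueError(f"need more than k={k} spots")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    _, idx = nn.kneighbors(pts)
    neighbor_labels = labels[idx[:, 1:]]
    discordant = (neighbor_labels != labels[:, None]).sum(axis=1)
    return float(np.mean(discordant >= threshold))


def lisi(
    labels: Sequence,
    coords: SpatialCoordinates | np.ndarray,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Per-spot local inverse Simpson index of domain labels.

    Gaussian neighbor weights over the ``3 * perplexity`` nearest spots are
    calibrated per spot (bisection on the kernel precision, tolerance 1e-5 on
    the entropy) so the weight entropy equals ``log(perplexity)``; the LISI
    of a spot is ``1 / sum_k p(k)^2`` over the label probabilities ``p``.
    """
    labels = np.asarray(labels)
    pts = _as_points(coords)
    n = labels.size
    n_neighbors = int(np.floor(3 * perplexity))
    if n <= n_neighbors:
        raise ValueError(f"need n > 3 * perplexity = {n_neighbors} spots")
    uniq, encoded = np.unique(labels, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pts)
    dists, idx = nn.kneighbors(pts)
    dists, idx = dists[:, 1:], idx[:, 1:]
    target = np.log(perplexity)
    out = np.full(n, np.nan)
    for i in range(n):
        d2 = dists[i] ** 2
        lo, hi = 0.0, np.inf
        beta = 1.0
        p = None
        for _ in range(100):
            w = np.exp(-beta * d2)
            s = w.sum()
            if s <= 0:
                hi = beta
                beta = 0.5 * (lo + beta)
                continue
            p = w / s
            entropy = -np.sum(p * np.log(np.clip(p, 1e-300, None)))
            if abs(entropy - target) < 1e-5:
                break
            if entropy > target:
                lo = beta
                beta = beta * 2 if np.isinf(hi) else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = 0.5 * (lo + beta)
        if p is None:
            warnings.warn(f"LISI calibration failed for spot {i}", stacklevel=2)
            continue
        pk = np.bincount(encoded[idx[i]], weights=p, minlength=uniq.size)
        out[i] = 1.0 / np.sum(pk**2)
    return out


def pseudo_r2_mcfadden(predictors: np.ndarray, truth: Sequence) -> float:
    """McFadden-adjusted pseudo-R^2 of a multinomial regression.

    Fits ``truth ~ predictors`` with intercepts and a small ridge penalty for
    stability, and returns ``1 - (lnL_model - K) / lnL_null`` where ``K`` is
    the number of estimated non-intercept parameters, ``p * (C - 1)``, and
    ``lnL_null`` the intercept-only log-likelihood.
    """
    X = np.atleast_2d(np.asarray(predictors, float))
    y = np.asarray(truth)
    classes, encoded = np.unique(y, return_inverse=True)
    n, p = X.shape
    n_classes = classes.size
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    model = LogisticRegression(C=100.0, max_iter=2000, solver="lbfgs").fit(X, encoded)
    prob = np.clip(model.predict_proba(X), 1e-12, None)
    ll_model = float(np.sum(np.log(prob[np.arange(n), encoded])))
    counts = np.bincount(encoded)
    ll_null = float(np.sum(counts * np.log(counts / n)))
    k_par = p * (n_classes - 1)
    return float(1.0 - (ll_model - k_par) / ll_null)


def metagene_enrichment(
    expr: ExpressionMatrix,
    truth: Sequence,
    detected: Sequence,
    overlap_min: float = 0.35,
    adj_p_max: float = 0.001,
) -> dict:
    """Per-true-domain metagene enrichment score of a detected labeling.

    For each true domain: genes up-regulated inside the domain (one-vs-rest
    rank-sum test, Benjamini-Hochberg adjusted p below ``adj_p_max``,
    positive fold change on the normalized values) define a metagene — the
    per-location mean of those genes, min-max scaled to [0, 1]. The detected
    domain sharing the largest fraction of its spots with the true domain
    (required >= ``overlap_min``) is matched to it, and the score is the mean
    metagene value inside the matched domain divided by the mean outside.
    Domains without DE genes or a qualifying match get ``None``.
    """
    truth, detected = _check_lengths(truth, detected)
    if expr.n_locations != truth.size:
        raise ValueError("expression and labels cover different locations")
    values = expr.values
    scores: dict = {}
    for dom in np.unique(truth):
        inside = truth == dom
        pvals, fold_pos = [], []
        for j in range(values.shape[0]):
            inside_vals, outside_vals = values[j, inside], values[j, ~inside]
            stat, pval = stats.ranksums(inside_vals, outside_vals)
            pvals.append(pval)
            fold_pos.append(inside_vals.mean() > outside_vals.mean())
        adj = multipletests(pvals, method="fdr_bh")[1]
        de_rows = np.where((adj < adj_p_max) & np.asarray(fold_pos))[0]
        if de_rows.size == 0:
            scores[dom] = None
            continue
        metagene = values[de_rows].mean(axis=0)
        lo, hi = metagene.min(), metagene.max()
        if hi > lo:
            metagene = (metagene - lo) / (hi - lo)
        else:
            metagene = np.full_like(metagene, 0.5)
        # match the detected domain with the highest overlap fraction
        best_label, best_frac = None, 0.0
        for det in np.unique(detected):
            det_mask = detected == det
            frac = np.sum(det_mask & inside) / det_mask.sum()
            if frac > best_frac:
                best_label, best_frac = det, frac
        if best_label is None or best_frac < overlap_min:
            scores[dom] = None
            continue
        match = detected == best_label
        outside_mean = metagene[~match].mean() if (~match).any() else np.nan
        if not np.isfinite(outside_mean) or outside_mean == 0:
            scores[dom] = None
            continue
        scores[dom] = float(metagene[match].mean() / outside_mean)
    return scores


def morans_i(
    values: Sequence[float],
    coords: SpatialCoordinates | np.ndarray,
    k: int = 10,
) -> float:
    """Moran's I with row-normalized binary k-nearest-neighbor weights.

    Under no spatial autocorrelation the expectation is ``-1/(n-1)``.
    """
    z = np.asarray(values, float)
    pts = _as_points(coords)
    n = z.size
    if np.allclose(z, z[0]):
        raise ValueError("Moran's I undefined for constant input")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    _, idx = nn.kneighbors(pts)
    idx = idx[:, 1:]
    zc = z - z.mean()
    lagged = zc[idx].mean(axis=1)  # row-normalized weights
    return float(np.sum(zc * lagged) / np.sum(zc**2))
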