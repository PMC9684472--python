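"""The spatially aware probabilistic PCA model.

The generative model for the standardized gene x location matrix ``Y`` is

    Y = (X B)^T + W Z + E,

with ``X`` an n x q covariate matrix (intercept only by default), ``W`` an
m x d orthonormal loading matrix, ``Z`` a d x n latent factor matrix whose
rows follow a Gaussian-process prior ``Z_l ~ MVN(0, sigma0^2 * tau * K)``
over the tissue locations, and iid residuals ``E_ji ~ N(0, sigma0^2)``.
``K`` is the spatial kernel built by :mod:`spatialpca.kernels`; ``tau``
measures the strength of the spatially structured signal relative to noise.

Integrating out ``B`` (by projecting the data onto the orthogonal complement
of ``X``) and ``Z`` leaves a marginal likelihood in which, after rotating
locations into the kernel eigenbasis ``K = U diag(lambda) U^T``, every
(factor, eigen-direction) pair is an independent Gaussian with variance
``sigma0^2 (1 + tau * lambda_k)`` and every remaining gene direction has
variance ``sigma0^2``. All quantities below exploit that diagonalization:

* the log-likelihood costs O(r (m d + n)) once ``W^T Y U`` is formed,
* for fixed ``tau`` the optimal ``W`` spans the top-d left singular space of
  ``(Y U) diag(sqrt(w_k))`` with ``w_k = tau lambda_k / (1 + tau lambda_k)``,
* ``sigma0^2`` profiles in closed form, and ``tau`` reduces to a 1-D search,
* the posterior mean of each factor is ``U diag(w_k) U^T (W^T Y)_l``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io import CovariateTable, ExpressionMatrix
from .kernels import SpatialKernel

__all__ = [
    "SpatialPCAFit",
    "project_covariates",
    "marginal_loglik",
    "fit",
    "posterior_spatial_pcs",
]

#: 1-D search grid for tau (log-spaced) before golden-section refinement
TAU_GRID = np.logspace(-10, 10, 21)
DEFAULT_D = 20


@dataclass
class SpatialPCAFit:
    """Estimated loadings, variance parameters and posterior factors."""

    W: np.ndarray
    tau: float
    sigma0_sq: float
    Z: np.ndarray
    d: int
    loglik: float
    kernel: SpatialKernel
    covariates: CovariateTable
    gene_ids: list[str]


def project_covariates(Y: np.ndarray, covariates: CovariateTable) -> np.ndarray:
    """Project data columns onto the orthogonal complement of X.

    Removing the covariate term this way is equivalent to integrating out the
    coefficients B under a flat prior; for an intercept-only X it amounts to
    centering each gene across locations.
    """
    X = covariates.values
    coef = np.linalg.solve(X.T @ X, (Y @ X).T)  # q x m
    return Y - coef.T @ X.T


def _check_params(W: np.ndarray, tau: float, sigma0_sq: float) -> None:
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if sigma0_sq <= 0:
        raise ValueError("sigma0_sq must be positive")
    d = W.shape[1]
    if np.max(np.abs(W.T @ W - np.eye(d))) > 1e-6:
        raise ValueError("W must have orthonormal columns")


def marginal_loglik(
    expr: ExpressionMatrix,
    kernel: SpatialKernel,
    W: np.ndarray,
    tau: float,
    sigma0_sq: float,
    covariates: CovariateTable | None = None,
) -> float:
    """Marginal log-likelihood of the covariate-projected data.

    The column-stacked projected matrix is multivariate normal with
    covariance ``sigma0^2 (tau * K (x) W W^T + I)``; evaluation is done in
    the kernel eigenbasis. With a truncated eigendecomposition the retained
    spectrum defines the model (``lambda_k = 0`` beyond rank r).
    """
    if expr.state != "standardized":
        raise ValueError("model operates on standardized expression")
    if kernel.eigvals is None or kernel.eigvecs is None:
        raise ValueError("kernel eigenpairs missing: run lowrank_eigen first")
    _check_params(W, tau, sigma0_sq)
    if covariates is None:
        covariates = CovariateTable.intercept_only(expr.n_locations)
    Y = project_covariates(expr.values, covariates)
    m, n = Y.shape
    d = W.shape[1]
    lam = kernel.eigvals
    w = tau * lam / (1.0 + tau * lam)
    B = (W.T @ Y) @ kernel.eigvecs  # d x r
    quad = float(np.sum(Y * Y)) - float(np.sum(w * np.sum(B * B, axis=0)))
    return float(
        -0.5 * m * n * np.log(2.0 * np.pi * sigma0_sq)
        - 0.5 * d * np.sum(np.log1p(tau * lam))
        - 0.5 * quad / sigma0_sq
    )


def _profile_at_tau(
    tau: float, C: np.ndarray, lam: np.ndarray, total_ss: float, m: int, n: int, d: int
) -> tuple[float, float, float]:
    """Profiled log-likelihood at tau; returns (loglik, sigma0_sq, explained)."""
    w = tau * lam / (1.0 + tau * lam)
    sv = np.linalg.svd(C * np.sqrt(w), compute_uv=False)
    explained = float(np.sum(sv[:d] ** 2))
    sigma0_sq = (total_ss - explained) / (m * n)
    if sigma0_sq <= 0:
        sigma0_sq = np.finfo(float).tiny
    ll = (
        -0.5 * m * n * (np.log(2.0 * np.pi * sigma0_sq) + 1.0)
        - 0.5 * d * np.sum(np.log1p(tau * lam))
    )
    return float(ll), float(sigma0_sq), explained


def fit(
    expr: ExpressionMatrix,
    kernel: SpatialKernel,
    d: int = DEFAULT_D,
    covariates: CovariateTable | None = None,
) -> SpatialPCAFit:
    """Maximum-likelihood fit of (W, tau, sigma0^2) and posterior factors.

    For each candidate ``tau`` the optimal loadings are the top-d
    eigenvectors of ``Y U diag(w) U^T Y^T`` (computed via the SVD of
    ``(Y U) diag(sqrt(w))``) and ``sigma0^2`` has a closed form; ``tau`` is
    found by a 21-point log-spaced grid search refined by golden-section,
    with ties broken toward the smaller value (weaker spatial prior). The
    fit is deterministic given its inputs.
    """
    if expr.state != "standardized":
        raise ValueError("model operates on standardized expression")
    if kernel.eigvals is None or kernel.eigvecs is None:
        raise ValueError("kernel eigenpairs missing: run lowrank_eigen first")
    m, n = expr.values.shape
    if not 0 < d < min(m, n):
        raise ValueError(f"d={d} must satisfy 0 < d < min(m, n) = {min(m, n)}")
    if covariates is None:
        covariates = CovariateTable.intercept_only(n)
    Y = project_covariates(expr.values, covariates)
    lam = kernel.eigvals
    U = kernel.eigvecs
    C = Y @ U  # m x r
    total_ss = float(np.sum(Y * Y))

    grid_ll = np.array(
        [_profile_at_tau(t, C, lam, total_ss, m, n, d)[0] for t in TAU_GRID]
    )
    if not np.all(np.isfinite(grid_ll)):
        raise RuntimeError("tau grid search produced non-finite log-likelihoods")
    best = int(np.argmax(grid_ll))  # argmax returns the first (smallest) tau on ties

    def neg_ll_log_tau(lt: float) -> float:
        return -_profile_at_tau(np.exp(lt), C, lam, total_ss, m, n, d)[0]

    log_grid = np.log(TAU_GRID)
    lo = log_grid[max(best - 1, 0)]
    hi = log_grid[min(best + 1, len(TAU_GRID) - 1)]
    mid = log_grid[best]
    if lo < mid < hi and grid_ll[best] > max(grid_ll[best - 1], grid_ll[best + 1]):
        res = optimize.minimize_scalar(
            neg_ll_log_tau, bracket=(lo, mid, hi), method="golden",
            options={"xtol": 1e-6},
        )
        tau_hat = float(np.exp(res.x)) if res.fun <= -grid_ll[best] else float(
            TAU_GRID[best]
        )
    else:
        # maximum at a grid boundary: refine within the adjacent interval
        res = optimize.minimize_scalar(
            neg_ll_log_tau, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        tau_hat = float(np.exp(res.x)) if res.fun <= -grid_ll[best] else float(
            TAU_GRID[best]
        )

    ll, sigma0_sq, _ = _profile_at_tau(tau_hat, C, lam, total_ss, m, n, d)
    w = tau_hat * lam / (1.0 + tau_hat * lam)
    Uw, sv, _ = np.linalg.svd(C * np.sqrt(w), full_matrices=False)
    if tau_hat * np.max(lam, initial=0.0) < 1e-12 or np.sum(sv > 1e-12) < d:
        # no usable spatial signal at this tau: fall back to the PCA basis of
        # the projected data so the returned loadings are still well defined
        Uw, sv, _ = np.linalg.svd(Y, full_matrices=False)
        if np.sum(sv > 1e-12) < d:
            raise ValueError(f"data rank is below the requested d={d}")
    W = Uw[:, :d]
    # sign convention: the largest-magnitude entry of each column is positive
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    W = W * signs

    A = W.T @ Y
    Z = ((A @ U) * w) @ U.T
    return SpatialPCAFit(
        W=W,
        tau=tau_hat,
        sigma0_sq=sigma0_sq,
        Z=Z,
        d=d,
        loglik=ll,
        kernel=kernel,
        covariates=covariates,
        gene_ids=list(expr.gene_ids),
    )


def posterior_spatial_pcs(
    fit: SpatialPCAFit, expr: ExpressionMatrix
) -> np.ndarray:
    """Posterior mean E[Z | Y] of the spatial PCs at the fitted parameters.

    For factor l the posterior mean is ``U diag(w_k) U^T a_l`` with ``a_l``
    the l-th row of ``W^T Y`` (projected data) and
    ``w_k = tau lambda_k / (1 + tau lambda_k)``.
    """
    if expr.values.shape[0] != fit.W.shape[0]:
        raise ValueError("expression gene count does not match the fit")
    if expr.values.shape[1] != fit.kernel.n:
        raise ValueError("expression location count does not match the kernel")
    Y = project_covariates(expr.values, fit.covariates)
    lam = fit.kernel.eigvals
    U = fit.kernel.eigvecs
    w = fit.tau * lam / (1.0 + fit.tau * lam)
    A = fit.W.T @ Y
    return ((A @ U) * w) @ U.T
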