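"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dense covariances, exhaustive pair
enumeration, breadth-first search — and shares no code with the package
implementations it is used to check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal


def dense_marginal_loglik(Yp, K, W, tau, sigma0_sq):
    """Log-density of the column-stacked projected data under the model."""
    m, n = Yp.shape
    cov = sigma0_sq * (np.kron(tau * K, W @ W.T) + np.eye(m * n))
    return multivariate_normal.logpdf(
        Yp.T.ravel(), mean=np.zeros(m * n), cov=cov, allow_singular=False
    )


def dense_posterior_mean(Yp, K, W, tau, sigma0_sq):
    """E[Z | Y] by explicit joint-Gaussian conditioning; returns d x n."""
    m, n = Yp.shape
    d = W.shape[1]
    cov_zy = sigma0_sq * np.kron(tau * K, W.T)  # (dn) x (mn)
    cov_yy = sigma0_sq * (np.kron(tau * K, W @ W.T) + np.eye(m * n))
    ez = cov_zy @ np.linalg.solve(cov_yy, Yp.T.ravel())
    return ez.reshape(n, d).T


def gp_conditional_mean(K_new_old, K_old, Z, jitter=0.0):
    """Kriging conditional mean, solved densely per factor."""
    A = K_old + jitter * np.eye(K_old.shape[0])
    return np.vstack([K_new_old @ np.linalg.solve(A, z) for z in Z])


def ari_pair_enumeration(a, b):
    """ARI by exhaustive enumeration of all location pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n00 = n01 = n10 = n11 = 0
    for i, j in combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def pas_bruteforce(labels, pts, k=10, threshold=6):
    labels = np.asarray(labels)
    pts = np.asarray(pts, float)
    n = labels.size
    abnormal = 0
    for i in range(n):
        dists = np.linalg.norm(pts - pts[i], axis=1)
        order = np.argsort(dists, kind="stable")
        neighbors = [j for j in order if j != i][:k]
        if sum(labels[j] != labels[i] for j in neighbors) >= threshold:
            abnormal += 1
    return abnormal / n


def chaos_bruteforce(labels, pts):
    labels = np.asarray(labels)
    pts = np.asarray(pts, float)
    total = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size < 2:
            continue
        for i in idx:
            dists = [np.linalg.norm(pts[i] - pts[j]) for j in idx if j != i]
            total += min(dists)
    return total / labels.size


def lisi_bruteforce(labels, pts, perplexity=10.0):
    """Per-spot inverse Simpson index with brentq-calibrated kernel width."""
    labels = np.asarray(labels)
    pts = np.asarray(pts, float)
    n = labels.size
    k = int(np.floor(3 * perplexity))
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        dists = np.linalg.norm(pts - pts[i], axis=1)
        order = [j for j in np.argsort(dists, kind="stable") if j != i][:k]
        d2 = dists[order] ** 2

        def entropy_gap(beta):
            w = np.exp(-beta * d2)
            p = w / w.sum()
            return -(p * np.log(p + 1e-300)).sum() - target

        lo, hi = 1e-12, 1.0
        while entropy_gap(hi) > 0:
            hi *= 2
        beta = optimize.brentq(entropy_gap, lo, hi, xtol=1e-12)
        w = np.exp(-beta * d2)
        p = w / w.sum()
        pk = {}
        for j, pj in zip(order, p):
            pk[labels[j]] = pk.get(labels[j], 0.0) + pj
        out[i] = 1.0 / sum(v * v for v in pk.values())
    return out


def bfs_hops(adjacency_sets, n):
    """All-pairs shortest hop counts by breadth-first search."""
    out = np.full((n, n), -1, dtype=int)
    for start in range(n):
        out[start, start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adjacency_sets[u]:
                if out[start, v] < 0:
                    out[start, v] = out[start, u] + 1
                    queue.append(v)
    return out
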