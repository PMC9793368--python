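"""Internal negative-binomial MLE engine.

Parametrization everywhere: NB(mean m, dispersion phi) with
Var = m + phi * m**2; phi = 0 is the Poisson limit.

Two fitting paths:

* equal size factors within the fitted cell set — the mean MLE is the
  sample mean divided by the shared size factor for *any* phi, so the
  2-D problem reduces to a 1-D profile likelihood in phi.  That profile
  is maximized for many genes at once with a coarse scan plus
  golden-section refinement, using a tail-count representation of the
  counts so each profile evaluation costs O(sum_g max_g) instead of
  O(G * n).
* general size factors — per-gene bounded quasi-Newton on
  (log mean, log phi), with the closed-form Poisson fit always compared
  as the phi = 0 boundary candidate.

All-zero input is the exact boundary case (mu, phi, loglik) = (0, 0, 0).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

PHI_MIN = 1e-8
PHI_MAX = 1e6
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden ratio step


def nb_loglik(x, s, mu, phi) -> float:
    """Sum of NB log pmfs of ``x`` with per-cell means ``s * mu``."""
    x = np.asarray(x, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), x.shape)
    m = s * mu
    if mu == 0:
        return 0.0 if np.all(x == 0) else -np.inf
    if phi == 0:
        return float(np.sum(x * np.log(m) - m - gammaln(x + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(x + r)
            - gammaln(r)
            - gammaln(x + 1)
            + r * np.log(r / (r + m))
            + x * np.log(m / (r + m))
        )
    )


class _TailCounts:
    """Flattened tail-count representation of an integer count matrix.

    For gene g and threshold j, ``T[g, j]`` is the number of cells with
    count > j (j = 0..max_g - 1).  Because
    ``gammaln(x + r) - gammaln(r) = sum_{j < x} log(r + j)`` for integer x,
    per-gene NB log-likelihood profiles can be evaluated from (T, n, m)
    alone, in time proportional to the number of (g, j) pairs.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X)
        G, n = X.shape
        self.G, self.n = G, n
        self.m = X.mean(axis=1)  # mean count per gene (= s0 * mu)
        gene_idx, js, tails = [], [], []
        for g in range(G):
            mx = int(X[g].max(initial=0))
            if mx == 0:
                continue
            b = np.bincount(X[g], minlength=mx + 1)
            tail = n - np.cumsum(b)[:-1]  # tail[j] = #cells with count > j
            keep = np.flatnonzero(tail > 0)
            gene_idx.append(np.full(keep.size, g, dtype=np.int64))
            js.append(keep.astype(np.float64))
            tails.append(tail[keep].astype(np.float64))
        if gene_idx:
            self.gene_idx = np.concatenate(gene_idx)
            self.j = np.concatenate(js)
            self.tail = np.concatenate(tails)
        else:
            self.gene_idx = np.empty(0, dtype=np.int64)
            self.j = np.empty(0)
            self.tail = np.empty(0)
        # sum_c gammaln(x_c + 1) = sum_j T_gj * log(j + 1)
        self.const = np.bincount(
            self.gene_idx, weights=self.tail * np.log(self.j + 1.0), minlength=G
        )

    def loglik_at_phi(self, t: np.ndarray) -> np.ndarray:
        """Per-gene NB log-likelihood at phi = exp(t), mean fixed at m."""
        r = np.exp(-t)  # 1 / phi
        w = self.tail * np.log(r[self.gene_idx] + self.j)
        term1 = np.bincount(self.gene_idx, weights=w, minlength=self.G)
        m, n = self.m, self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                term1
                - self.const
                - n * r * np.log1p(m / r)
                + n * m * np.log(m / (r + m))
            )
        ll[m == 0] = 0.0
        return ll

    def loglik_poisson(self) -> np.ndarray:
        m, n = self.m, self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = n * m * np.log(m) - n * m - self.const
        ll[m == 0] = 0.0
        return ll


def _profile_phi(tc: _TailCounts, n_scan: int = 13, n_golden: int = 40):
    """Maximize the phi profile for all genes; returns (phi_hat, loglik)."""
    G = tc.G
    lo, hi = np.log(PHI_MIN), np.log(PHI_MAX)
    grid = np.linspace(lo, hi, n_scan)
    scan = np.empty((n_scan, G))
    for i, t in enumerate(grid):
        scan[i] = tc.loglik_at_phi(np.full(G, t))
    best = np.argmax(scan, axis=0)
    step = grid[1] - grid[0]
    a = np.maximum(grid[best] - step, lo)
    b = np.minimum(grid[best] + step, hi)

    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = tc.loglik_at_phi(x1)
    f2 = tc.loglik_at_phi(x2)
    for _ in range(n_golden):
        right = f2 >= f1
        a = np.where(right, x1, a)
        b = np.where(right, b, x2)
        x1n = np.where(right, x2, b - _INVPHI * (b - a))
        x2n = np.where(right, a + _INVPHI * (b - a), x1)
        f1n = np.where(right, f2, 0.0)
        f2n = np.where(right, 0.0, f1)
        probe = np.where(right, x2n, x1n)
        fprobe = tc.loglik_at_phi(probe)
        f1 = np.where(right, f1n, fprobe)
        f2 = np.where(right, fprobe, f2n)
        x1, x2 = x1n, x2n
    t_hat = (a + b) / 2.0
    ll_hat = tc.loglik_at_phi(t_hat)
    phi_hat = np.exp(t_hat)

    # phi = 0 boundary: prefer the Poisson fit when it is at least as good
    ll_pois = tc.loglik_poisson()
    pois = ll_pois >= ll_hat - 1e-9
    phi_hat = np.where(pois, 0.0, phi_hat)
    ll_hat = np.where(pois, ll_pois, ll_hat)
    zero = tc.m == 0
    phi_hat[zero] = 0.0
    ll_hat[zero] = 0.0
    return phi_hat, ll_hat


def fit_nb_many(X: np.ndarray, s: np.ndarray):
    """MLE of (mu, phi) for every gene (row) of ``X`` given size factors.

    Returns arrays ``(mu, phi, loglik, converged)`` of length ``G``.
    """
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    s = np.broadcast_to(np.asarray(s, dtype=float), (X.shape[1],))
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    G = X.shape[0]
    if np.ptp(s) <= 1e-12 * s[0]:
        tc = _TailCounts(X)
        phi, ll = _profile_phi(tc)
        mu = tc.m / s[0]
        return mu, phi, ll, np.ones(G, dtype=bool)
    mu = np.empty(G)
    phi = np.empty(G)
    ll = np.empty(G)
    conv = np.empty(G, dtype=bool)
    for g in range(G):
        mu[g], phi[g], ll[g], conv[g] = fit_nb_single(X[g], s)
    return mu, phi, ll, conv


def fit_nb_single(x: np.ndarray, s: np.ndarray, max_iter: int = 500):
    """MLE of (mu, phi) for one count vector with general size factors."""
    x = np.asarray(x, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), x.shape)
    if np.all(x == 0):
        return 0.0, 0.0, 0.0, True
    if np.ptp(s) <= 1e-12 * s[0]:
        mu, phi, ll, conv = fit_nb_many(x.astype(np.int64)[None, :], s)
        return float(mu[0]), float(phi[0]), float(ll[0]), bool(conv[0])

    sum_x, sum_s = x.sum(), s.sum()
    mu_pois = sum_x / sum_s  # exact Poisson MLE with offsets
    ll_pois = nb_loglik(x, s, mu_pois, 0.0)

    mean_x, var_x = x.mean(), x.var(ddof=1) if x.size > 1 else 0.0
    phi0 = max(1e-3, (var_x - mean_x) / mean_x**2) if mean_x > 0 else 1e-3

    def neg_ll(theta):
        return -nb_loglik(x, s, np.exp(theta[0]), np.exp(theta[1]))

    bounds = [(np.log(1e-12), np.log(1e9)), (np.log(PHI_MIN), np.log(PHI_MAX))]
    best = None
    converged = False
    for init_phi in (phi0, 1.0):
        res = minimize(
            neg_ll,
            x0=[np.log(max(mu_pois, 1e-10)), np.log(min(max(init_phi, PHI_MIN), PHI_MAX))],
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    mu_hat, phi_hat = np.exp(best.x)
    ll_hat = -best.fun
    if ll_pois >= ll_hat - 1e-9:
        return float(mu_pois), 0.0, float(ll_pois), True
    return float(mu_hat), float(phi_hat), float(ll_hat), converged
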