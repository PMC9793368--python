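"""Negative-binomial and zero-inflated NB models for UMI counts.

The NB parametrization used throughout the package is mean/dispersion with
``Var = m + phi * m**2``; ``phi = 0`` is the Poisson limit.  This is the
unique parametrization consistent with the working-dispersion identity
``xi = (sigma^2 - mu) / mu^2`` used for feature selection.

The module covers six distribution families used to characterize UMI
counts:

* monoclonal (no cell-type structure): gene-common NB/ZINB (one dispersion
  — and for ZINB one zero-inflation probability — shared across genes) and
  gene-specific NB/ZINB;
* polyclonal: cell-type-common NB (per-gene parameters pooled across
  clusters) and cell-type-specific NB (per gene and cluster).

Library size enters through per-cell size factors ``s_c`` multiplying the
mean, so cell ``c`` of gene ``g`` in cluster ``k`` is modeled as
``NB(s_c * mu_gk, phi_gk)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from ._engine import PHI_MAX, PHI_MIN, fit_nb_many, fit_nb_single, nb_loglik
from .io import CountMatrix, LabelSet, StructuralError

__all__ = [
    "SizeFactors",
    "NBFit",
    "FAMILIES",
    "compute_size_factors",
    "nb_log_pmf",
    "zinb_log_pmf",
    "fit_nb_cell",
    "fit_family",
    "predict_zero_proportions",
]

FAMILIES = (
    "gene-common-nb",
    "gene-common-zinb",
    "gene-specific-nb",
    "gene-specific-zinb",
    "cell-type-common-nb",
    "cell-type-specific-nb",
)


@dataclass
class SizeFactors:
    """Per-cell positive scale factors; ``definition`` records the choice."""

    s: np.ndarray
    definition: str = "library-size/median"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0) or not np.all(np.isfinite(self.s)):
            raise ValueError("size factors must be positive and finite")

    def __len__(self) -> int:
        return self.s.size

    def __getitem__(self, idx) -> np.ndarray:
        return self.s[idx]


def compute_size_factors(counts: CountMatrix, method: str = "median") -> SizeFactors:
    """Library-size size factors over the genes present in ``counts``.

    ``method='median'`` (default): ``s_c = lib_c / median(lib)``, so the
    median size factor is exactly 1.  ``method='mean'`` divides by the mean
    library size instead.
    """
    lib = counts.values.sum(axis=0).astype(float)
    if np.any(lib == 0):
        cell = counts.cell_ids[int(np.flatnonzero(lib == 0)[0])]
        raise ValueError(f"cell {cell!r} has zero total count")
    if method == "median":
        return SizeFactors(lib / np.median(lib), "library-size/median")
    if method == "mean":
        return SizeFactors(lib / lib.mean(), "library-size/mean")
    raise ValueError(f"unknown size-factor method {method!r}")


def _as_s(size_factors, n_cells: int) -> np.ndarray:
    if size_factors is None:
        return np.ones(n_cells)
    s = size_factors.s if isinstance(size_factors, SizeFactors) else np.asarray(size_factors, dtype=float)
    return np.broadcast_to(s, (n_cells,))


def nb_log_pmf(x, mean, dispersion):
    """NB log pmf under the mean/dispersion parametrization.

    ``Var = mean + dispersion * mean**2``; ``dispersion = 0`` returns the
    Poisson log pmf, and ``mean = 0`` returns 0 at x = 0 and -inf otherwise.
    Broadcasts over all arguments.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a non-negative integer")
    if np.any(m < 0):
        raise ValueError("mean must be non-negative")
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")
    scalar = np.ndim(x) == 0 and np.ndim(m) == 0 and np.ndim(phi) == 0
    x, m, phi = np.atleast_1d(*np.broadcast_arrays(x, m, phi))
    out = np.empty(x.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        # below ~1e-8 the gammaln difference loses more precision than the
        # Poisson limit differs from the NB pmf; use the limit directly
        pois = phi <= 1e-8
        out[pois] = x[pois] * np.log(m[pois]) - m[pois] - gammaln(x[pois] + 1)
        nb = ~pois
        r = 1.0 / phi[nb]
        out[nb] = (
            gammaln(x[nb] + r)
            - gammaln(r)
            - gammaln(x[nb] + 1)
            - r * np.log1p(m[nb] / r)
            + x[nb] * np.log(m[nb] / (r + m[nb]))
        )
    # mean 0: point mass at zero
    zero_mean = m == 0.0
    out[zero_mean] = np.where(x[zero_mean] == 0.0, 0.0, -np.inf)
    return float(out[0]) if scalar else out


def zinb_log_pmf(x, mean, dispersion, zero_prob):
    """Zero-inflated NB log pmf, computed stably in log space.

    ``log[ pi0 * 1{x=0} + (1 - pi0) * NB(x | mean, dispersion) ]`` with
    ``0 <= pi0 < 1``.
    """
    pi0 = np.asarray(zero_prob, dtype=float)
    if np.any(pi0 < 0) or np.any(pi0 >= 1):
        raise ValueError("zero_prob must lie in [0, 1)")
    scalar = np.ndim(x) == 0 and np.ndim(mean) == 0 and np.ndim(dispersion) == 0 and pi0.ndim == 0
    base = np.atleast_1d(nb_log_pmf(x, mean, dispersion))
    x_b, pi_b, base = np.atleast_1d(
        *np.broadcast_arrays(np.asarray(x, dtype=float), pi0, base)
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_b)  # -inf where pi0 == 0
        out = np.log1p(-pi_b) + base
        out = np.where(x_b == 0.0, np.logaddexp(log_pi, out), out)
    return float(out[0]) if scalar else out


def fit_nb_cell(x, size_factors=None):
    """NB MLE for one (gene, cell set) count vector.

    Maximizes ``sum_c log NB(x_c | s_c * mu, phi)`` over ``mu >= 0`` and
    ``phi in [0, 1e6]``.  All-zero input is the exact boundary case
    ``(0, 0, loglik=0)``.  Returns ``(mu, phi, loglik, converged)``.
    """
    x = np.asarray(x)
    s = _as_s(size_factors, x.size)
    return fit_nb_single(x, s)


@dataclass
class NBFit:
    """Fitted parameters for one distribution family.

    ``params`` has one row per fitted (gene[, cluster]) unit with columns
    ``gene, cluster, mu, phi, pi0, loglik, n_cells, converged``; monoclonal
    families use cluster 0.  ``total_loglik`` is the maximized
    log-likelihood summed over all fitted cells.
    """

    family: str
    params: pd.DataFrame
    total_loglik: float = field(init=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.total_loglik = float(self.params["loglik"].sum())


def _zinb_negll(x, s, log_mu, log_phi, logit_pi):
    mu = np.exp(log_mu)
    phi = np.exp(log_phi)
    pi0 = 1.0 / (1.0 + np.exp(-logit_pi))
    return -float(np.sum(zinb_log_pmf(x, s * mu, phi, pi0)))


def _fit_zinb_single(x, s):
    """Per-gene ZINB MLE on (log mu, log phi, logit pi0)."""
    x = np.asarray(x, dtype=float)
    if np.all(x == 0):
        return 0.0, 0.0, 0.0, 0.0, True
    mu0 = max(x.sum() / s.sum(), 1e-8)
    mean_x = x.mean()
    var_x = x.var(ddof=1) if x.size > 1 else 0.0
    phi0 = min(max((var_x - mean_x) / mean_x**2, 1e-3), PHI_MAX) if mean_x > 0 else 1e-3

    def obj(theta):
        return _zinb_negll(x, s, *theta)

    res = minimize(
        obj,
        x0=[np.log(mu0), np.log(phi0), -2.0],
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
    )
    mu, phi = np.exp(res.x[0]), np.exp(res.x[1])
    pi0 = 1.0 / (1.0 + np.exp(-res.x[2]))
    ll = -res.fun
    # NB is the pi0 -> 0 boundary of ZINB; never report a worse fit
    mu_nb, phi_nb, ll_nb, conv_nb = fit_nb_single(x, s)
    if ll_nb >= ll:
        return mu_nb, phi_nb, 0.0, ll_nb, conv_nb
    return float(mu), float(phi), float(pi0), float(ll), bool(res.success)


def _profile_mu_given_phi(x, s, phi, pi0=None):
    """Per-gene 1-D mean update used by the gene-common profile fits."""
    if np.all(x == 0) and pi0 in (None, 0.0):
        return 0.0, 0.0
    if phi == 0 and pi0 in (None, 0.0):
        mu = x.sum() / s.sum()
        return mu, nb_loglik(x, s, mu, 0.0)

    def negll(log_mu):
        mu = np.exp(log_mu)
        if pi0 is None:
            return -nb_loglik(x, s, mu, phi)
        return -float(np.sum(zinb_log_pmf(x, s * mu, phi, pi0)))

    mu0 = max(x.sum() / s.sum(), 1e-8)
    res = minimize_scalar(
        negll, bounds=(np.log(1e-10), np.log(max(10 * mu0, 1.0))), method="bounded",
        options={"xatol": 1e-10},
    )
    cand = [(float(np.exp(res.x)), float(-res.fun))]
    if np.all(x == 0):
        # mu = 0 boundary: the fitted distribution is a point mass at zero
        cand.append((0.0, 0.0))
    return max(cand, key=lambda t: t[1])


def _fit_gene_common(X, s, zinb: bool):
    """Profile likelihood: outer search over the shared dispersion (and
    shared zero-inflation for ZINB), inner per-gene mean updates."""
    G = X.shape[0]

    def profile_ll(phi, pi0=None):
        mus = np.empty(G)
        lls = np.empty(G)
        if np.ptp(s) <= 1e-12 * s[0] and pi0 is None:
            # equal size factors: mean MLE is the sample mean for any phi
            mus = X.mean(axis=1) / s[0]
            for g in range(G):
                lls[g] = nb_loglik(X[g], s, mus[g], phi)
        else:
            for g in range(G):
                mus[g], lls[g] = _profile_mu_given_phi(X[g], s, phi, pi0)
        return mus, float(lls.sum()), lls

    if not zinb:
        res = minimize_scalar(
            lambda t: -profile_ll(np.exp(t))[1],
            bounds=(np.log(PHI_MIN), np.log(PHI_MAX)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        phi_hat, pi_hat = float(np.exp(res.x)), 0.0
        mus, total, lls = profile_ll(phi_hat)
        # compare with the Poisson boundary
        mus0, total0, lls0 = profile_ll(0.0)
        if total0 >= total:
            phi_hat, mus, lls = 0.0, mus0, lls0
    else:
        res = minimize(
            lambda th: -profile_ll(np.exp(th[0]), 1.0 / (1.0 + np.exp(-th[1])))[1],
            x0=[np.log(0.5), -2.0],
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8},
        )
        phi_hat = float(np.exp(res.x[0]))
        pi_hat = float(1.0 / (1.0 + np.exp(-res.x[1])))
        mus, total, lls = profile_ll(phi_hat, pi_hat)
        # pi0 = 0 boundary: ZINB nests gene-common NB, never report worse
        mus_nb, phi_nb, _, lls_nb = _fit_gene_common(X, s, zinb=False)
        if lls_nb.sum() >= total:
            phi_hat, pi_hat, mus, lls = phi_nb, 0.0, mus_nb, lls_nb
    return mus, phi_hat, pi_hat, lls


def fit_family(
    counts: CountMatrix,
    labels: LabelSet | None,
    family: str,
    size_factors: SizeFactors | None = None,
) -> NBFit:
    """Fit one of the six UMI count distribution families.

    Monoclonal families (``gene-common-*``, ``gene-specific-*``) ignore
    ``labels``; the two cell-type families require them.  Clusters with a
    single cell are fitted but flagged through ``converged``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    X = counts.values
    s = _as_s(size_factors, counts.n_cells)
    rows = []

    if family in ("cell-type-common-nb", "cell-type-specific-nb"):
        if labels is None:
            raise StructuralError(f"family {family!r} requires a label set")
        if labels.labels.size != counts.n_cells:
            raise StructuralError("label set length does not match the cell count")
        if family == "cell-type-common-nb":
            mu, phi, ll, conv = fit_nb_many(X, s)
            for g in range(counts.n_genes):
                rows.append((counts.gene_ids[g], 0, mu[g], phi[g], 0.0, ll[g],
                             counts.n_cells, conv[g]))
        else:
            for k in range(1, labels.K + 1):
                idx = labels.cluster_cells(k)
                if idx.size == 0:
                    raise StructuralError(f"cluster {k} has no cells")
                if idx.size == 1:
                    warnings.warn(f"cluster {k} has a single cell; boundary fit")
                mu, phi, ll, conv = fit_nb_many(X[:, idx], s[idx])
                for g in range(counts.n_genes):
                    rows.append((counts.gene_ids[g], k, mu[g], phi[g], 0.0, ll[g],
                                 idx.size, conv[g] and idx.size > 1))
    elif family == "gene-specific-nb":
        mu, phi, ll, conv = fit_nb_many(X, s)
        for g in range(counts.n_genes):
            rows.append((counts.gene_ids[g], 0, mu[g], phi[g], 0.0, ll[g],
                         counts.n_cells, conv[g]))
    elif family == "gene-specific-zinb":
        for g in range(counts.n_genes):
            mu, phi, pi0, ll, conv = _fit_zinb_single(X[g], s)
            rows.append((counts.gene_ids[g], 0, mu, phi, pi0, ll, counts.n_cells, conv))
    else:  # gene-common families
        mus, phi_hat, pi_hat, lls = _fit_gene_common(X, s, zinb=family == "gene-common-zinb")
        for g in range(counts.n_genes):
            rows.append((counts.gene_ids[g], 0, mus[g], phi_hat, pi_hat, lls[g],
                         counts.n_cells, True))

    params = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "mu", "phi", "pi0", "loglik", "n_cells", "converged"],
    )
    return NBFit(family=family, params=params)


def predict_zero_proportions(
    fit: NBFit,
    test: CountMatrix,
    test_labels: LabelSet | None = None,
    size_factors: SizeFactors | None = None,
) -> pd.DataFrame:
    """Expected vs observed zero proportions of held-out cells.

    For each fitted (gene[, cluster]) unit the expected zero proportion is
    the NB (or ZINB) zero probability averaged over the test cells' size
    factors; the observed value is the empirical zero fraction.  Returns a
    table with the difference ``observed - expected`` per unit.
    """
    s = _as_s(size_factors, test.n_cells)
    gene_pos = {g: i for i, g in enumerate(test.gene_ids)}
    specific = fit.family == "cell-type-specific-nb"
    if specific and test_labels is None:
        raise StructuralError("cell-type-specific predictions require test labels")
    # with test labels, every family is assessed within each benchmark
    # cluster (one row per gene per cluster); families without cell-type
    # parameters reuse their gene-level fit in every cluster
    out = []
    for row in fit.params.itertuples(index=False):
        if row.gene not in gene_pos:
            warnings.warn(f"gene {row.gene!r} absent from the test matrix; skipped")
            continue
        g = gene_pos[row.gene]
        if specific:
            cluster_idx = [(int(row.cluster), test_labels.cluster_cells(int(row.cluster)))]
        elif test_labels is not None:
            cluster_idx = [
                (k, test_labels.cluster_cells(k)) for k in range(1, test_labels.K + 1)
            ]
        else:
            cluster_idx = [(0, np.arange(test.n_cells))]
        for k, idx in cluster_idx:
            if idx.size == 0:
                continue
            x = test.values[g, idx]
            means = s[idx] * row.mu
            if row.pi0 > 0:
                log_p0 = zinb_log_pmf(np.zeros_like(means), means, row.phi, row.pi0)
            else:
                log_p0 = nb_log_pmf(np.zeros_like(means), means, row.phi)
            expected = float(np.mean(np.exp(log_p0)))
            observed = float(np.mean(x == 0))
            out.append((row.gene, k, expected, observed, observed - expected))
    return pd.DataFrame(
        out, columns=["gene", "cluster", "expected_zero", "observed_zero", "difference"]
    )
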