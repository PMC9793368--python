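"""Clustering Deviation Index (CDI).

For a candidate label set L with K clusters over G feature genes and N
cells, the single-batch model is ``X_gc | L_c = k ~ NB(s_c mu_gk, phi_gk)``
with per-cell size factors s_c.  The maximized log-likelihood lhat sums
the per-(gene, cluster) NB MLE log-likelihoods, and

    CDI = -2 * lhat + c_pen * d,

with ``c_pen = 2`` (CDI-AIC) or ``log(N)`` (CDI-BIC) and degrees of
freedom ``d = sum_gk d_gk``.  Single-batch data have ``d_gk = 2`` (a mean
and a dispersion), so ``d = 2 G K``.

For multi-batch data, each (gene, cluster) is tested for a batch effect
with a likelihood-ratio test of

    H0_gk: mu_gk^(1) = ... = mu_gk^(B),  phi_gk^(1) = ... = phi_gk^(B)

against batch-specific parameters (2(B - 1) degrees of freedom, using
only the batches represented in the cluster).  Rejected units keep
batch-specific parameters (d_gk = 2B); accepted units are pooled
(d_gk = 2).

The candidate with the lowest CDI is optimal: CDI-BIC penalizes cluster
number more heavily and targets main-type resolution, CDI-AIC targets
subtype resolution.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._engine import fit_nb_many, fit_nb_single
from .io import REPORT_COLUMNS, CountMatrix, LabelSet, StructuralError
from .nb_model import SizeFactors, _as_s

__all__ = ["CDIScore", "BatchTestResult", "batch_effect_lrt", "compute_cdi", "rank_label_sets"]


@dataclass
class BatchTestResult:
    """Likelihood-ratio test of one (gene, cluster) batch effect."""

    gene: str
    cluster: int
    statistic: float
    df: int
    p_value: float
    rejected: bool
    n_batches: int  # batches represented in this cluster


@dataclass
class CDIScore:
    """CDI of one candidate label set.

    ``aic = -2 lhat + 2 d`` and ``bic = -2 lhat + log(N) d`` share the same
    maximized log-likelihood and degrees of freedom, so
    ``bic - aic = (log(N) - 2) * d`` exactly.
    """

    name: str
    K: int
    n_cells: int
    loglik: float
    d: int
    aic: float
    bic: float
    batch_tests: pd.DataFrame | None = None
    gene_list_hash: str = ""


def _gene_hash(gene_ids) -> str:
    h = hashlib.sha256("\n".join(gene_ids).encode())
    return h.hexdigest()[:12]


def batch_effect_lrt(
    x,
    batches,
    size_factors=None,
    alpha: float = 0.05,
    gene: str = "",
    cluster: int = 0,
) -> BatchTestResult:
    """LRT of a common NB (mean, dispersion) across batches for one gene's
    counts within one cluster.

    The statistic is twice the log-likelihood gain of batch-specific fits
    over the pooled fit, compared to chi-squared with 2(B - 1) degrees of
    freedom, B being the number of batches with at least one cell here.
    """
    x = np.asarray(x)
    batches = np.asarray(batches)
    s = _as_s(size_factors, x.size)
    levels = [b for b in pd.unique(batches) if np.any(batches == b)]
    if len(levels) < 2:
        raise StructuralError("batch-effect LRT requires >= 2 represented batches")
    ll_pooled = fit_nb_single(x, s)[2]
    ll_split = 0.0
    for b in levels:
        idx = batches == b
        ll_split += fit_nb_single(x[idx], s[idx])[2]
    stat = max(2.0 * (ll_split - ll_pooled), 0.0)
    df = 2 * (len(levels) - 1)
    p = float(chi2.sf(stat, df))
    return BatchTestResult(
        gene=gene,
        cluster=cluster,
        statistic=float(stat),
        df=df,
        p_value=p,
        rejected=p < alpha,
        n_batches=len(levels),
    )


def _score_single_batch(counts, labels, s):
    """(loglik, d) summed in fixed gene order within each cluster."""
    total = 0.0
    for k in range(1, labels.K + 1):
        idx = labels.cluster_cells(k)
        if idx.size == 0:
            raise StructuralError(f"cluster {k} has no cells")
        _, _, ll, _ = fit_nb_many(counts.values[:, idx], s[idx])
        total += float(ll.sum())
    return total, 2 * counts.n_genes * labels.K, None


def _score_multi_batch(counts, labels, s, alpha):
    X = counts.values
    batch = counts.batch
    total = 0.0
    d = 0
    tests = []
    for k in range(1, labels.K + 1):
        idx = labels.cluster_cells(k)
        if idx.size == 0:
            raise StructuralError(f"cluster {k} has no cells")
        sub_batch = batch[idx]
        levels = [b for b in pd.unique(sub_batch)]
        present = [b for b in levels if np.any(sub_batch == b)]
        if len(present) < len(pd.unique(batch)):
            warnings.warn(
                f"cluster {k}: only {len(present)} of "
                f"{len(pd.unique(batch))} batches represented; the test and "
                "degrees of freedom use the represented batches"
            )
        _, _, ll_pooled, _ = fit_nb_many(X[:, idx], s[idx])
        if len(present) < 2:
            total += float(ll_pooled.sum())
            d += 2 * counts.n_genes
            continue
        ll_split = np.zeros(counts.n_genes)
        for b in present:
            bidx = idx[sub_batch == b]
            _, _, ll_b, _ = fit_nb_many(X[:, bidx], s[bidx])
            ll_split += ll_b
        stat = np.maximum(2.0 * (ll_split - ll_pooled), 0.0)
        df = 2 * (len(present) - 1)
        pvals = chi2.sf(stat, df)
        rejected = pvals < alpha
        for g in range(counts.n_genes):
            tests.append(
                (counts.gene_ids[g], k, float(stat[g]), df, float(pvals[g]),
                 bool(rejected[g]), len(present))
            )
        total += float(np.where(rejected, ll_split, ll_pooled).sum())
        d += int(np.where(rejected, 2 * len(present), 2).sum())
    tests = pd.DataFrame(
        tests,
        columns=["gene", "cluster", "statistic", "df", "p_value", "rejected", "n_batches"],
    )
    return total, d, tests


def compute_cdi(
    counts: CountMatrix,
    labels: LabelSet,
    size_factors: SizeFactors | None = None,
    batch_alpha: float = 0.05,
) -> CDIScore:
    """CDI-AIC and CDI-BIC of one candidate label set.

    ``counts`` should already be restricted to the selected feature genes
    — the index is defined on feature genes, and scores are comparable
    only within one gene set (recorded via ``gene_list_hash``).  Batch
    labels on ``counts`` switch on the per-(gene, cluster) batch-effect
    test at level ``batch_alpha``.
    """
    if labels.labels.size != counts.n_cells:
        raise StructuralError("label set length does not match the cell count")
    s = _as_s(size_factors, counts.n_cells)
    multi = counts.batch is not None and len(counts.batch_levels) > 1
    if multi:
        loglik, d, tests = _score_multi_batch(counts, labels, s, batch_alpha)
    else:
        loglik, d, tests = _score_single_batch(counts, labels, s)
    n = counts.n_cells
    return CDIScore(
        name=labels.name,
        K=labels.K,
        n_cells=n,
        loglik=loglik,
        d=d,
        aic=-2.0 * loglik + 2.0 * d,
        bic=-2.0 * loglik + np.log(n) * d,
        batch_tests=tests,
        gene_list_hash=_gene_hash(counts.gene_ids),
    )


def rank_label_sets(
    counts: CountMatrix,
    candidates: list[LabelSet],
    size_factors: SizeFactors | None = None,
    batch_alpha: float = 0.05,
) -> tuple[pd.DataFrame, str, str]:
    """Score candidates and flag the CDI-AIC and CDI-BIC optima.

    Returns ``(report, best_aic_name, best_bic_name)`` with the report
    sorted by CDI-BIC.  Duplicate candidate names are disambiguated with
    numeric suffixes.  Fewer than ten candidates triggers a warning: a
    reliable selection needs a reasonably large candidate pool.
    """
    if not candidates:
        raise ValueError("at least one candidate label set is required")
    if len(candidates) < 10:
        warnings.warn(
            f"only {len(candidates)} candidate label sets; selection is more "
            "reliable with at least ten"
        )
    seen: dict[str, int] = {}
    rows = []
    scores = []
    for cand in candidates:
        name = cand.name
        if name in seen:
            seen[name] += 1
            name = f"{name}_{seen[cand.name]}"
            warnings.warn(f"duplicate candidate name {cand.name!r} renamed to {name!r}")
        else:
            seen[name] = 1
        score = compute_cdi(counts, cand, size_factors, batch_alpha)
        score.name = name
        scores.append(score)
        rows.append(
            (name, score.K, -2.0 * score.loglik, score.d, score.aic, score.bic)
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    best_aic = report.loc[report["CDI_AIC"].idxmin(), "label_set"]
    best_bic = report.loc[report["CDI_BIC"].idxmin(), "label_set"]
    report["is_aic_optimal"] = report["label_set"] == best_aic
    report["is_bic_optimal"] = report["label_set"] == best_bic
    report = report.sort_values("CDI_BIC", kind="stable").reset_index(drop=True)
    return report, str(best_aic), str(best_bic)
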