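"""Working-dispersion-score (WDS) feature selection.

The working dispersion score of gene g is the method-of-moments dispersion
estimate pooling all cells,

    xi_g = (sigma_g^2 - mu_g) / mu_g^2,

where mu_g and sigma_g^2 are the sample mean and (unbiased, n-1
denominator) sample variance of the gene's UMI counts.  Under a common
NB(mu, phi) with Var = mu + phi * mu^2 it estimates phi; across a mixture
of cell types it inflates with the between-type mean fold change, which is
what makes it a feature-gene score.  Genes with more than 95% zero counts
are removed before scoring.

Single-batch data keep the top ``n_features`` genes by score.  Multi-batch
data rank genes within each batch (rank 1 = highest score), take each
gene's minimum rank across batches as its overall rank, and keep the genes
with the smallest overall rank — so a gene highly variable in *any* batch
is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "WDSResult",
    "filter_genes_by_zero_prop",
    "compute_wds",
    "select_feature_genes",
    "rank_by_min_batch_rank",
]


class NoGenesError(ValueError):
    """Every gene was removed by the zero-proportion filter."""


@dataclass
class WDSResult:
    """Per-gene WDS summary with the selected feature genes."""

    table: pd.DataFrame  # gene, mean, variance, wds [, one rank column per batch]
    selected: list[str]


def filter_genes_by_zero_prop(
    counts: CountMatrix, max_zero_prop: float = 0.95
) -> CountMatrix:
    """Drop genes whose zero-count proportion exceeds ``max_zero_prop``.

    The rule is strict: a gene is removed only when *more than* the given
    fraction of its counts are zero, so a gene at exactly the threshold is
    retained.  Cell set and gene order are unchanged.
    """
    if not 0 < max_zero_prop <= 1:
        raise ValueError("max_zero_prop must lie in (0, 1]")
    zero_prop = np.mean(counts.values == 0, axis=1)
    keep = np.flatnonzero(zero_prop <= max_zero_prop)
    if keep.size == 0:
        raise NoGenesError(
            f"no genes survive the zero-proportion filter at {max_zero_prop}"
        )
    return counts.subset_genes(keep)


def compute_wds(counts: CountMatrix) -> np.ndarray:
    """Per-gene working dispersion score over all cells.

    Requires every gene to have a positive mean (run the zero filter
    first); a zero-mean gene has an undefined score and raises.
    """
    X = counts.values
    mean = X.mean(axis=1)
    if np.any(mean == 0):
        gene = counts.gene_ids[int(np.flatnonzero(mean == 0)[0])]
        raise ValueError(f"gene {gene!r} has zero mean; WDS is undefined")
    var = X.var(axis=1, ddof=1)
    return (var - mean) / mean**2


def _dense_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank genes by score descending; rank 1 = highest.  Ties broken by
    input gene order (stable sort), deterministically."""
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(scores.size, dtype=np.int64)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


def rank_by_min_batch_rank(rank_matrix: np.ndarray) -> np.ndarray:
    """Combine per-batch ranks (genes x batches) into a selection order.

    Each gene's overall rank is its minimum rank across batches; genes are
    ordered by overall rank, ties broken by input gene order.  Returns the
    gene indices in selection order.
    """
    overall = np.asarray(rank_matrix).min(axis=1)
    return np.argsort(overall, kind="stable")


def wds_summary(counts: CountMatrix) -> WDSResult:
    """WDS table with per-batch scores and ranks when batches are present."""
    X = counts.values
    table = pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "mean": X.mean(axis=1),
            "variance": X.var(axis=1, ddof=1),
            "wds": compute_wds(counts),
        }
    )
    if counts.batch is not None and len(counts.batch_levels) > 1:
        for level in counts.batch_levels:
            sub = counts.subset_cells(counts.cells_in_batch(level))
            scores = compute_wds(sub) if np.all(sub.values.mean(axis=1) > 0) else _safe_wds(sub)
            table[f"wds_batch_{level}"] = scores
            table[f"rank_batch_{level}"] = _dense_ranks(scores)
    return WDSResult(table=table, selected=[])


def _safe_wds(counts: CountMatrix) -> np.ndarray:
    """WDS with zero-mean genes scored -inf (never selected) — used for
    per-batch scoring where a gene may be all-zero in one batch."""
    X = counts.values
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wds = (var - mean) / mean**2
    wds[mean == 0] = -np.inf
    return wds


def select_feature_genes(
    counts: CountMatrix,
    n_features: int = 500,
    feature_genes: list[str] | None = None,
) -> list[str]:
    """Select feature genes by WDS, in rank order.

    A manual ``feature_genes`` list bypasses scoring entirely.  With batch
    labels on ``counts`` the min-rank-across-batches rule is used.  If
    fewer than ``n_features`` genes are available, all are returned with a
    warning.
    """
    if feature_genes is not None:
        known = set(counts.gene_ids)
        missing = [g for g in feature_genes if g not in known]
        if missing:
            raise ValueError(f"manual feature genes not in matrix: {missing[:5]}")
        return list(feature_genes)
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_features > counts.n_genes:
        warnings.warn(
            f"requested {n_features} feature genes but only {counts.n_genes} "
            "genes are available; returning all"
        )
        n_features = counts.n_genes

    if counts.batch is not None and len(counts.batch_levels) > 1:
        ranks = np.column_stack(
            [
                _dense_ranks(_safe_wds(counts.subset_cells(counts.cells_in_batch(b))))
                for b in counts.batch_levels
            ]
        )
        order = rank_by_min_batch_rank(ranks)
    else:
        order = np.argsort(-compute_wds(counts), kind="stable")
    return [counts.gene_ids[i] for i in order[:n_features]]
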