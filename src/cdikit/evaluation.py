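"""External indices and the rank-agreement protocol.

External indices (ARI, Fowlkes-Mallows, NMI) compare a candidate label
set against a benchmark from their contingency table; all three equal 1
for identical partitions up to relabeling.

The rank-agreement protocol scores an internal index against an external
one over a pool of L candidate label sets: the internal scores are
negated when lower is better, both vectors are converted to ranks
(average ranks for ties), and the Pearson correlation of the rank vectors
— the Spearman correlation — is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
)

from .io import LabelSet

__all__ = ["AgreementInput", "external_indices", "spearman_agreement"]


@dataclass
class AgreementInput:
    """Paired internal/external scores over the same candidate pool."""

    internal: np.ndarray
    external: np.ndarray
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        self.internal = np.asarray(self.internal, dtype=float)
        self.external = np.asarray(self.external, dtype=float)
        if self.internal.shape != self.external.shape or self.internal.ndim != 1:
            raise ValueError("score vectors must be 1-D and of equal length")
        if self.internal.size < 2:
            raise ValueError("need at least two candidates")
        if np.any(~np.isfinite(self.internal)) or np.any(~np.isfinite(self.external)):
            raise ValueError("score vectors must not contain missing values")


def _labels(a) -> np.ndarray:
    return a.labels if isinstance(a, LabelSet) else np.asarray(a)


def external_indices(a, b) -> tuple[float, float, float]:
    """(ARI, Fowlkes-Mallows, NMI) between two label sets."""
    la, lb = _labels(a), _labels(b)
    if la.size != lb.size:
        raise ValueError("label sets have different lengths")
    return (
        float(adjusted_rand_score(la, lb)),
        float(fowlkes_mallows_score(la, lb)),
        float(normalized_mutual_info_score(la, lb)),
    )


def spearman_agreement(agreement: AgreementInput) -> float:
    """Spearman correlation between internal and external index scores.

    Internal scores are negated first when the internal index marks better
    label sets with smaller values, so +1 always means perfect agreement.
    A constant score vector leaves the correlation undefined and raises.
    """
    internal = -agreement.internal if agreement.lower_is_better else agreement.internal
    if np.ptp(internal) == 0 or np.ptp(agreement.external) == 0:
        raise ValueError("constant score vector: Spearman correlation is undefined")
    rho = spearmanr(agreement.external, internal).statistic
    return float(rho)
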