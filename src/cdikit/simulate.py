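"""Seeded NB population simulators.

Counts for cell type k and gene g are drawn from NB(mu_gk, phi_gk) under
the mean/dispersion parametrization (Var = mu + phi * mu^2).  Baseline
mean and dispersion parameters are drawn per gene from normal
distributions truncated at zero from below; each non-baseline group
applies a constant log2 fold change to the means of its feature genes and
a Gaussian shift (clamped at a small positive floor) to their dispersions.

Three preset designs are provided:

* SD1 — ten equal groups of 400 cells (4,000 cells, 10,000 genes);
  baseline mu ~ TN(0.2, 0.1), phi ~ TN(0.5, 0.1); each of the nine
  non-baseline groups has 25 disjoint feature genes at log2 FC 2.4 with
  dispersion shifts N(0, 0.05).
* SD2 — two abundant types (2,000 cells each) and two rare types (100
  cells each, configurable RC1 size); feature blocks of 40/50/50 genes at
  log2 FC 1.5 / 2.8 / 3.2.
* SD3 — hierarchical: main type C1 (1,000 homogeneous cells, baseline
  mu ~ TN(0.4, 0.1), phi ~ TN(1, 0.1)) and main type C2 (three subtypes of
  600 cells).  Each subtype carries 40 feature genes: 30 shared by all
  subtypes at log2 FC 4 (separating the main types) and 10 exclusive at
  log2 FC 1.8 (separating the subtypes).

All presets accept size overrides so tests can run scaled-down versions;
the defaults are the study designs above.  Counts are drawn without
library-size variation by default (all size factors equal 1); the
``library_size_sigma`` option multiplies per-cell means by lognormal
factors, and ``outlier_fraction`` inflates the means of a random subset of
cells to emulate model misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import CountMatrix, LabelSet

__all__ = [
    "Group",
    "FeatureBlock",
    "SimSpec",
    "SimResult",
    "simulate_population",
    "make_sd1_spec",
    "make_sd2_spec",
    "make_sd3_spec",
]

_PHI_FLOOR = 1e-6


@dataclass
class Group:
    name: str
    n_cells: int
    parent: str | None = None  # main-type name for hierarchical designs


@dataclass
class FeatureBlock:
    """Feature genes of one group: a constant log2 fold change on means and
    a Gaussian dispersion shift."""

    group: str
    gene_indices: np.ndarray
    log2_fc: float
    dispersion_shift_sd: float = 0.05


@dataclass
class SimSpec:
    """Full parameterization of one NB population simulation."""

    groups: list[Group]
    n_genes: int
    mean_dist: tuple[float, float] = (0.2, 0.1)  # TruncNormal(mean, sd, lower 0)
    dispersion_dist: tuple[float, float] = (0.5, 0.1)
    feature_blocks: list[FeatureBlock] = field(default_factory=list)
    seed: int = 0
    n_batches: int = 1
    library_size_sigma: float = 0.0
    outlier_fraction: float = 0.0
    name: str = "custom"

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            if g.n_cells < 1:
                raise ValueError(f"group {g.name!r} must have >= 1 cell")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for dist in (self.mean_dist, self.dispersion_dist):
            if dist[0] <= 0 or dist[1] <= 0:
                raise ValueError("distribution parameters must be positive")
        for fb in self.feature_blocks:
            if fb.group not in names:
                raise ValueError(f"feature block references unknown group {fb.group!r}")
            idx = np.asarray(fb.gene_indices)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ValueError("feature-gene indices out of range")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")


@dataclass
class SimResult:
    """A simulated population with its ground truth."""

    counts: CountMatrix
    labels: LabelSet  # finest-resolution truth
    features: pd.DataFrame  # gene_index, gene_id, group, log2_fc
    main_labels: LabelSet | None = None  # main-type truth for hierarchical designs
    true_means: np.ndarray | None = None  # genes x groups
    true_dispersions: np.ndarray | None = None


def _truncnorm_positive(rng, mean, sd, size):
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _nb_draw(rng, mu, phi):
    """Draw NB(mu, phi) counts; phi = 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(np.broadcast_shapes(mu.shape, phi.shape), dtype=np.int64)
    mu, phi = np.broadcast_arrays(mu, phi)
    pois = phi < _PHI_FLOOR
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if np.any(nb):
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_population(spec: SimSpec) -> SimResult:
    """Draw a count matrix, true labels, and feature-gene truth table.

    Deterministic given ``spec.seed``: all randomness flows through one
    ``numpy.random.default_rng`` stream.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    n_groups = len(spec.groups)

    base_mu = _truncnorm_positive(rng, *spec.mean_dist, G)
    base_phi = _truncnorm_positive(rng, *spec.dispersion_dist, G)

    mus = np.tile(base_mu[:, None], (1, n_groups))
    phis = np.tile(base_phi[:, None], (1, n_groups))
    group_pos = {g.name: i for i, g in enumerate(spec.groups)}
    feat_rows = []
    for fb in spec.feature_blocks:
        j = group_pos[fb.group]
        idx = np.asarray(fb.gene_indices, dtype=int)
        mus[idx, j] = base_mu[idx] * 2.0**fb.log2_fc
        shift = rng.normal(0.0, fb.dispersion_shift_sd, idx.size)
        phis[idx, j] = np.maximum(base_phi[idx] + shift, _PHI_FLOOR)
        for gi in idx:
            feat_rows.append((int(gi), f"gene{gi + 1:05d}", fb.group, fb.log2_fc))

    n_cells = sum(g.n_cells for g in spec.groups)
    X = np.empty((G, n_cells), dtype=np.int64)
    labels = np.empty(n_cells, dtype=np.int64)
    main = np.empty(n_cells, dtype=object)
    col = 0
    for j, g in enumerate(spec.groups):
        cols = slice(col, col + g.n_cells)
        cell_mu = np.broadcast_to(mus[:, j][:, None], (G, g.n_cells))
        if spec.library_size_sigma > 0:
            size = np.exp(rng.normal(0.0, spec.library_size_sigma, g.n_cells))
            cell_mu = cell_mu * size[None, :]
        X[:, cols] = _nb_draw(rng, cell_mu, phis[:, j][:, None])
        labels[cols] = j + 1
        main[cols] = g.parent if g.parent is not None else g.name
        col += g.n_cells

    if spec.outlier_fraction > 0:
        n_out = int(round(spec.outlier_fraction * n_cells))
        out_cells = rng.choice(n_cells, size=n_out, replace=False)
        for c in out_cells:
            j = labels[c] - 1
            X[:, c] = _nb_draw(rng, 5.0 * mus[:, j], phis[:, j])

    batch = None
    if spec.n_batches > 1:
        batch = np.array([f"batch{(c % spec.n_batches) + 1}" for c in range(n_cells)])

    counts = CountMatrix(
        X,
        [f"gene{i + 1:05d}" for i in range(G)],
        [f"cell{c + 1:05d}" for c in range(n_cells)],
        batch,
    )
    features = pd.DataFrame(
        feat_rows, columns=["gene_index", "gene_id", "group", "log2_fc"]
    ).drop_duplicates(subset=["gene_index", "group"])
    truth = LabelSet(labels, name=f"{spec.name}-truth")
    main_truth = None
    if any(g.parent is not None for g in spec.groups):
        main_truth = LabelSet.from_raw(main.astype(str), name=f"{spec.name}-main-truth")
    return SimResult(
        counts=counts,
        labels=truth,
        features=features,
        main_labels=main_truth,
        true_means=mus,
        true_dispersions=phis,
    )


def _disjoint_feature_indices(rng, n_genes, block_sizes):
    total = sum(block_sizes)
    if total > n_genes:
        raise ValueError(
            f"the design needs {total} disjoint feature genes but the pool "
            f"has only {n_genes}; keep n_genes >= {total}"
        )
    pool = rng.choice(n_genes, size=total, replace=False)
    blocks, at = [], 0
    for size in block_sizes:
        blocks.append(np.sort(pool[at : at + size]))
        at += size
    return blocks


def make_sd1_spec(
    seed: int = 0,
    n_genes: int = 10_000,
    cells_per_group: int = 400,
    n_groups: int = 10,
    n_feature_genes: int = 25,
    log2_fc: float = 2.4,
) -> SimSpec:
    """Ten equal cell groups; nine carry disjoint 25-gene feature blocks."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    groups = [Group(f"G{j + 1}", cells_per_group) for j in range(n_groups)]
    blocks = _disjoint_feature_indices(rng, n_genes, [n_feature_genes] * (n_groups - 1))
    feature_blocks = [
        FeatureBlock(f"G{j + 2}", idx, log2_fc) for j, idx in enumerate(blocks)
    ]
    return SimSpec(
        groups=groups,
        n_genes=n_genes,
        mean_dist=(0.2, 0.1),
        dispersion_dist=(0.5, 0.1),
        feature_blocks=feature_blocks,
        seed=seed,
        name="sd1",
    )


def make_sd2_spec(
    rc1_cells: int = 100,
    seed: int = 0,
    n_genes: int = 10_000,
    abundant_cells: int = 2000,
    rc2_cells: int = 100,
) -> SimSpec:
    """Two abundant and two rare cell types; ``rc1_cells`` reproduces the
    rare-type reduction experiments (100 -> 85 -> 20 cells)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    groups = [
        Group("A1", abundant_cells),
        Group("A2", abundant_cells),
        Group("RC1", rc1_cells),
        Group("RC2", rc2_cells),
    ]
    b_a2, b_rc1, b_rc2 = _disjoint_feature_indices(rng, n_genes, [40, 50, 50])
    feature_blocks = [
        FeatureBlock("A2", b_a2, 1.5),
        FeatureBlock("RC1", b_rc1, 2.8),
        FeatureBlock("RC2", b_rc2, 3.2),
    ]
    return SimSpec(
        groups=groups,
        n_genes=n_genes,
        mean_dist=(0.2, 0.1),
        dispersion_dist=(0.5, 0.1),
        feature_blocks=feature_blocks,
        seed=seed,
        name="sd2",
    )


def make_sd3_spec(
    seed: int = 0,
    n_genes: int = 10_000,
    c1_cells: int = 1000,
    subtype_cells: int = 600,
) -> SimSpec:
    """Hierarchical design: homogeneous main type C1 plus main type C2 with
    three subtypes sharing 30 feature genes (log2 FC 4, main-type split)
    and carrying 10 exclusive feature genes each (log2 FC 1.8)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    groups = [
        Group("C1", c1_cells, parent="C1"),
        Group("C2a", subtype_cells, parent="C2"),
        Group("C2b", subtype_cells, parent="C2"),
        Group("C2c", subtype_cells, parent="C2"),
    ]
    shared, ex_a, ex_b, ex_c = _disjoint_feature_indices(rng, n_genes, [30, 10, 10, 10])
    feature_blocks = [
        FeatureBlock("C2a", shared, 4.0),
        FeatureBlock("C2b", shared, 4.0),
        FeatureBlock("C2c", shared, 4.0),
        FeatureBlock("C2a", ex_a, 1.8),
        FeatureBlock("C2b", ex_b, 1.8),
        FeatureBlock("C2c", ex_c, 1.8),
    ]
    return SimSpec(
        groups=groups,
        n_genes=n_genes,
        mean_dist=(0.4, 0.1),
        dispersion_dist=(1.0, 0.1),
        feature_blocks=feature_blocks,
        seed=seed,
        name="sd3",
    )
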