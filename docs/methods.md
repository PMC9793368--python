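# Methods

## Model

UMI counts from droplet protocols are modeled as negative binomial (NB) in
the mean/dispersion parametrization: X ~ NB(m, φ) with E[X] = m and
Var[X] = m + φm². φ = 0 is the Poisson limit, implemented exactly (the NB
formula is replaced by the Poisson log pmf for φ ≤ 1e−8, below which the
gammaln difference loses more precision than the limit differs from the NB).
This parametrization is the unique one consistent with the working
dispersion score ξ = (σ² − μ)/μ², whose plug-in estimate with the sample
mean and the unbiased (n−1) sample variance scores genes for feature
selection. A zero-inflated variant mixes a point mass at zero with weight
π₀ ∈ [0, 1); it exists to *test* whether UMI counts need zero inflation
(they generally do not), not as the default model.

Library size enters through per-cell size factors multiplying the mean:
cell c of gene g in cluster k is NB(s_c·μ_gk, φ_gk). The default size
factor is the cell's total count over the supplied genes divided by the
median such total (so the median size factor is exactly 1); a mean-based
alternative is selectable, and every report records the definition used.
Counts must be raw UMI counts: normalized quantities (FPKM/TPM) and read
counts with PCR duplicates violate the model and are out of scope.

## Distribution families

Six families cover the fitting and calibration workflows. For monoclonal
(single-type) populations: gene-common NB/ZINB share one dispersion (and,
for ZINB, one zero-inflation probability) across genes with gene-specific
means, fitted by profile likelihood (outer 1-D search over the shared
dispersion, inner per-gene mean updates); gene-specific NB/ZINB fit each
gene independently. For polyclonal populations: cell-type-common NB pools
cells across clusters per gene; cell-type-specific NB fits each
(gene, cluster) independently. Maximized log-likelihoods are monotone
along the nesting relations (common ⊂ specific, NB ⊂ ZINB), which the test
suite asserts.

## Maximum likelihood

When the size factors within a fitted cell set are equal, the mean MLE is
the sample mean divided by the shared size factor for *every* dispersion
value, so the 2-D problem reduces to a 1-D profile in φ. The profile is
maximized by a 13-point log-scale scan over φ ∈ [1e−8, 1e6] followed by 40
golden-section iterations, vectorized over genes through a tail-count
representation of the data (for integer x,
lnΓ(x+r) − lnΓ(r) = Σ_{j<x} ln(r+j), so the per-gene profile costs
O(max count) per evaluation instead of O(cells)). The φ = 0 Poisson fit is
always evaluated and preferred when at least as good, making the boundary
exact. With unequal size factors the fit is a bounded quasi-Newton
(L-BFGS-B) on (log μ, log φ) from moment initialization, with the
closed-form Poisson solution μ̂ = Σx/Σs as boundary candidate; iteration
cap 500, objective tolerance 1e−12, non-convergence flagged, never silent.
All-zero input is the exact boundary case (μ̂, φ̂, ℓ̂) = (0, 0, 0) — it
still counts the full d_gk = 2 degrees of freedom in CDI.

## CDI

For a candidate label set with K clusters over G feature genes and N cells,
CDI = −2ℓ̂ + c_pen·d with c_pen = 2 (AIC) or ln N (BIC), d = Σ_gk d_gk,
d_gk = 2 for single-batch data. ℓ̂ and d are pure sums over genes in fixed
input order, so results are independent of any work partitioning, scores on
disjoint gene sets add, and relabeling clusters changes nothing. Reports
record a hash of the gene list: CDI values are comparable only within one
feature-gene set. CDI-BIC targets main-type resolution, CDI-AIC subtype
resolution; with both, hierarchical structure can be read off a single
candidate pool.

Multi-batch data: for each (gene, cluster) the hypothesis of equal batch
parameters is tested by a likelihood-ratio test (statistic twice the
log-likelihood gain of per-batch fits over the pooled fit, χ² with 2(B−1)
degrees of freedom at level α = 0.05 by default, per (g,k) without
multiplicity correction — each decision only chooses that unit's
parametrization, and the level is configurable). Rejection keeps
batch-specific parameters (d_gk = 2B); acceptance pools. Clusters missing
from some batches are tested over the represented batches only, with the
degrees of freedom reduced to match — d then counts exactly the free
parameters. Size factors are computed globally, not per batch.

## Feature selection

Genes with more than 95% zero counts are removed first (strictly more
than: a gene at the threshold stays). Single-batch data keep the top
G₁ = 500 genes by WDS; multi-batch data rank genes within each batch
(rank 1 = highest), take each gene's minimum rank across batches, and keep
the smallest overall ranks — a gene highly variable in any one batch is
kept. Ties break by input gene order, deterministically. Manual gene lists
bypass scoring. WDS assumes no strong mean–dispersion trend; for data with
such trends (typical of bulk RNA-seq and of some simulators) it favors
weakly expressed genes and a different selector should be used.

## Binned goodness-of-fit test

Cells are cross-classified into the five count categories
{0}, {1}, {2}, {3}, [4, ∞) by K₀ benchmark clusters. Per gene, the Pearson
statistic T = Σ (n_Uk − Nπ̂_Uk)²/(Nπ̂_Uk) uses π̂_Uk = (N_k/N)·p̄_Uk(μ̂, φ̂),
where cluster proportions are plugged in as known, p̄ is the NB bin
probability averaged over the cluster's cells' size factors (a
`use_size_factors=False` flag gives the plain iid reading), and (μ̂, φ̂)
maximize the binned multinomial likelihood (Nelder-Mead on (log μ, log φ)
from moment starts, the same optimizer settings as the NB machinery).

Degrees of freedom: because each cluster's five bin counts sum to its own
fixed cluster size, T is a sum of K₀ independent per-cluster Pearson
statistics, giving K₀·(5−1) − p degrees of freedom (p = 2K₀ for the
cell-type-specific family, 2 for cell-type-common). This per-cluster
accounting is the default; simulation at the sparse-count regime typical
of these data (2,000 genes, 3 clusters × 500 cells, means ≈ 0.2) puts its
rejection rate at a nominal 5% level near 3–4%, whereas the alternative
single-multinomial accounting 5K₀ − p − 1 (`df_rule='published'`, counting
one sum-to-one constraint) rejects at only ~1.5% for K₀ = 3. The residual
conservatism of the default is a property of the fixed bin scheme at low
expression — the upper bins carry expected counts near or below one, where
the χ² approximation degrades. Genes whose smallest expected bin count
falls below 1e−8·N are flagged untestable and excluded from rejection-rate
denominators rather than producing inflated statistics. The monoclonal
(K₀ = 1) test reuses the same bin scheme, where both df rules agree.

## Zero-proportion calibration

`gof-calibrate` splits cells 50/50 uniformly at random (logged seed), fits
a family on the training half, and compares expected against observed zero
proportions per gene on the held-out half — per benchmark cluster when
labels are given, for every family (families without cell-type parameters
reuse their gene-level fit in each cluster). A family that matches the
data leaves the differences centered at zero; a family missing cell-type
structure shows systematic, sign-coherent deviations within clusters.

## Simulators

`simulate_population` draws counts gene-by-gene, group-by-group from
NB(μ_gk, φ_gk), deterministically from a single seeded generator stream.
Baseline means and dispersions are drawn per gene from normal
distributions truncated at zero from below; non-baseline groups share the
baseline parameters except on their feature-gene blocks, which apply a
constant log2 fold change to means and an independent Gaussian shift
(sd 0.05, floored at 1e−6) to dispersions. Feature blocks of different
groups are disjoint, drawn uniformly from the gene pool. Three preset
designs are provided (their defaults are the study conditions; size
overrides exist for scaled-down tests, and the block structure is kept
exact — a pool too small for the blocks is an error):

* ten equal groups of 400 cells, 10,000 genes, baseline μ ~ TN(0.2, 0.1),
  φ ~ TN(0.5, 0.1), nine groups with 25 feature genes at log2 FC 2.4;
* two abundant types (2,000 cells) and two rare types (100 cells,
  RC1 size configurable to 85 or 20 for the rare-type reduction
  experiments) with 40/50/50 feature genes at log2 FC 1.5/2.8/3.2;
* a hierarchical design: 1,000 homogeneous cells (μ ~ TN(0.4, 0.1),
  φ ~ TN(1, 0.1)) versus three subtypes of 600 cells, each with 30 shared
  feature genes at log2 FC 4 (main-type split) and 10 exclusive at
  log2 FC 1.8 (subtype split); both truth layers are returned.

By default all size factors are 1 (no library-size variation); a
`library_size_sigma` option multiplies per-cell means by lognormal factors
and `outlier_fraction` inflates a random subset of cells' means fivefold to
emulate model misspecification. What the simulator does *not* emulate:
ambient RNA, doublets, batch-specific chemistry, mean–dispersion trends,
or continuous (trajectory-like) populations — passing tests demonstrate
correctness of the statistical machinery under the NB model, not
robustness to every artifact of real data.

### A note on the ten-group design

Under these exact conditions the weakest group separations (25 genes at
log2 FC 2.4 from baseline means near 0.2) carry an expected deviance gain
of ≈ 4,300 for the tenth cluster — above the CDI-AIC penalty for 500 extra
(gene, cluster) units (2,000) but *below* the CDI-BIC penalty
(2·500·ln 4000 ≈ 8,300). Consequently CDI-AIC selects the true ten
clusters on this design while CDI-BIC settles on nine, merging the
cheapest group into the baseline; this is a property of the penalty
arithmetic, verified against a brute-force likelihood oracle, not an
artifact of the optimizer or the candidate pool (the true label set itself
scores a higher BIC than the best nine-cluster merge). The package reports
both selections.

## Evaluation protocol

External indices (ARI, Fowlkes-Mallows, NMI) are computed from the
contingency table via scikit-learn; an independent hand-written
contingency implementation serves as the oracle in the test suite. The
rank-agreement protocol negates internal scores when lower is better,
ranks both vectors (average ranks on ties — the standard Spearman
convention), and returns the Pearson correlation of the rank vectors, so
+1 always means perfect agreement; constant score vectors raise instead of
silently returning 0.

## Problem sizes used in the checks

The automated checks run the generators at their design sizes where the
quantity checked is the design itself (population arithmetic, selection
over a 28-candidate pool on the ten-group design across five seeds) and at
reduced gene counts where only statistical behavior is under test
(feature-gene recall at 2,000 genes, calibration at 2,000 genes × 1,500
cells, nulls at 500 replicates). Each check states its sizes in its code.

## Known limitations

* CDI requires raw UMI counts and candidate label sets; it does not
  produce clusterings, and its selection is only as good as the pool
  (ten or more candidates recommended).
* Scores are comparable only within one feature-gene set.
* The binned GoF test is mildly conservative at very low expression (see
  above) and its bins are fixed.
* Dispersion estimation is plain MLE per (gene, cluster); no shrinkage.
  One-cell clusters fit at the boundary and are flagged.
* The batch LRT tests mean/dispersion shifts only; batch effects that
  change distribution shape in other ways are invisible to it.
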