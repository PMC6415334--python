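# Methods

## Synthetic data

### Two-group negative-binomial simulation

The baseline negative control is a 500-gene × 1000-cell count matrix with
two equal cell groups. Gene base means sit on a deterministic log-spaced
grid over [10⁻³, 10⁴] expected counts per cell, giving reproducible
expression strata for the stratified correlation report. A configurable
fraction of genes (default one half) is differentially expressed by a fixed
fold (default 10); DE genes are spread evenly across the grid and alternate
direction, so half are high in each group and the two groups' expected
library sizes balance — non-DE genes are then a clean null for both the
correlation screen and the DE test. Counts are drawn independently per cell
from NB(μ, size) with `dispersion_size` exposed (default 1.0, variance
μ+μ²); the NB size of single-cell counts varies widely in practice and 1.0
is a mid-range choice. There is no library-size variation and no added
dropout in this design: zeros arise only from NB sampling, so a
well-behaved zero-imputer should leave the data essentially unchanged.
Replicate r uses seed `base_seed + r`; identical configuration and seed
give bit-identical matrices.

### Splat-style grouped simulation

The richer generator follows the standard gamma-Poisson layering: gene
means ~ Gamma(shape 0.6, rate 0.3); per-cell library sizes ~ log-normal
(meanlog 11, sdlog 0.2); per-group expected profiles are the gene means
with multiplicative DE factors applied (default 10-fold, alternating up
`de_factor` / down `1/de_factor`, assigned round-robin over groups),
renormalized to proportions and scaled by each cell's library size; counts
~ NB with size 1/bcv² (bcv 0.2). In `paths` mode each cell sits at a
uniform position u ∈ [0,1] along a log-linear interpolation from the
common origin profile to its group's anchor profile — the simplest
continuous-differentiation reading of the grouped model. Groups are always
equally sized, so the cell count must be divisible by the group count
(the package uses 999 cells when three equal types are required).

Technical dropout is a logistic layer on the log expected count: entry
(g, c) is replaced by zero with probability
`logistic(shape · (ln μ_gc − midpoint))`, shape < 0 (default −1), and the
event is recorded in a dropout mask (a subset of the zero entries).
Because the realized zero fraction depends on every other parameter, the
package treats the midpoint as a calibrated quantity:
`calibrate_dropout_midpoint` simulates the base counts once, bisects the
midpoint against the expected zero fraction
`mean((count==0) + (count>0)·p_drop)` — smooth and strictly increasing in
the midpoint — and converges to a fifth of the requested tolerance, so the
residual error on a fresh seed is dominated by Monte-Carlo variation
(≲0.3 percentage points at 2×10⁶ entries). Calibration, not any particular
default, is the contract for reaching a target sparsity level (e.g. 70, 80,
88 or 94% zeros); targets at or below the base zero fraction are rejected,
since dropout can only add zeros.

`simulate_matched_pair` draws two datasets from one ground truth by
separating the truth RNG (gene means, DE assignment; keyed by the config
seed) from the noise RNG (library sizes, counts, dropout; keyed by a noise
seed), optionally with different dropout severities — emulating one tissue
profiled on a deep, low-dropout platform and a sparse, high-dropout one.

What the generators deliberately do not model: batch effects, doublets,
cell-size confounding, and any attempt at byte-level agreement with
external simulators. Passing tests on this synthetic data therefore shows
that an imputer manufactures (or does not manufacture) signal out of pure
noise structure; it does not bound an imputer's behaviour under real-data
confounders, which the source experiments found to be substantially worse.

## Imputer archetypes

All archetypes preserve matrix shape and gene/cell order, and compute cell
neighbourhoods on Euclidean distance over all genes in log2(CPM+1) — no PCA
step, for determinism.

* **knn_smooth(k)** replaces each cell's profile with the sum of raw counts
  over itself and its k nearest neighbours (default k = n_cells/20).
  Library sizes grow ≈(k+1)-fold; k=0 is the identity.
* **diffusion(k=12, t=3)** builds a symmetrized adaptive-Gaussian knn
  affinity (per-cell bandwidth = distance to the k-th neighbour, affinities
  averaged, unit self-affinity), row-normalizes it to a Markov operator P,
  and applies t steps of P to the CPM matrix. t=0 returns CPM unchanged.
  Each diffusion step is a convex combination of cell values, so per-gene
  spread within a connected component contracts monotonically in t;
  disconnected components diffuse independently (with a warning). t is
  fixed rather than algorithmically chosen, exposed as a parameter. No
  post-diffusion rescaling is applied: every downstream test is rank-based,
  so monotone scaling is irrelevant.
* **model_zeros(threshold=0.5)** clusters cells (given labels, or k-means
  on the top-10 PCs of log2-CPM with a fixed seed when only a cluster
  count is supplied), then per gene and cluster fits a two-component
  mixture on log2-CPM by EM — Gamma for the dropout pile-up near zero
  (moment-matched weighted updates), Normal for expressed values (σ floored
  at 0.01). Entries with posterior dropout probability above the threshold
  are replaced by the cluster mean of expressed-classified entries,
  back-transformed to counts; everything else keeps its original value.
  Genes with fewer than 5 non-zero values in a cluster are skipped; EM
  stops at 100 iterations if unconverged (keeping the last estimate).

These are mechanisms, not replicas: the published tools' internal metrics
and normalizations are unspecified, so the archetypes reproduce the *class*
of behaviour (weighted-sum smoothing, diffusion smoothing, mixture-model
zero imputation) under one transparent set of conventions.

## Statistical conventions

* Working scale for every rank test: log2(count/libsize·10⁶ + 1). The
  inverse transform rounds to the nearest non-negative integer count.
* Spearman ρ is Pearson on mid-ranks; two-sided p from the t approximation
  with n−2 df. Constant genes are excluded from the tested family (and the
  family size m reflects that). Bonferroni q = min(1, m·p).
* Mann-Whitney-U: exact enumeration when both groups ≤ 8 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction (exposed as a flag; the correction matters near the lenient
  p > 0.2 screening threshold). All-tied inputs give p = 1.
* Kruskal-Wallis: tie-corrected H, χ² p with (groups−1) df; with two groups
  it coincides with the MWU normal approximation without continuity
  correction.
* BH adjustment is the standard step-up with monotonicity enforcement;
  adjusted values never fall below raw ones.
* All tests are two-sided: DE can go either way, and the experiments care
  about the existence of a difference, not its direction (direction is
  reported separately in the bias summary).

## Experiment protocols

**False correlations.** Impute, screen all gene pairs, Bonferroni at
q < 0.05, classify. TP requires both genes DE *and* sign concordance
(same DE direction → positive ρ, opposite → negative); everything else —
including any pair touching a non-DE gene — is FP. Strata are five
log-spaced bins of the truth's base means; a pair contributes to the
stratum of each member.

**Permutation null.** Filter (drop unlabelled cells and cell-types under
5% of cells, then genes detected in under 5% of remaining cells — cells
first, then genes; at least two types must survive), select the two
cell-types with the closest mean log2-CPM profiles (Euclidean; log scale
avoids library-size domination; ties break lexicographically), screen each
gene by MWU between the pair, and permute genes with raw p > 0.2
independently across the pair's cells on log2-CPM. Independent per-gene
permutation destroys residual gene-gene as well as gene-type structure
among the nulls. Permuted values are de-normalized with each receiving
cell's original library size, which keeps expression proportional to
library size (so no library-size signal is created) at the cost of small
per-cell library-size fluctuations from the permuted genes' contributions,
plus integer rounding. The re-test Bonferroni family is the permuted genes
only — they are the known-null hypotheses whose expected false-positive
count the protocol bounds below one; correcting over all genes is available
as a flag. The bias summary reports, per permuted gene, the sign of the
post-imputation mean difference and the fraction of directional genes
sharing the majority sign (≈1 for a systematic bias, ≈0.5 for random
directions).

**DE benchmark.** Kruskal-Wallis per gene on log2-CPM, BH, call at
q ≤ 0.05; effect = max |log2FC| over group pairs; sensitivity/specificity
against truth; ROC curves swept over raw p thresholds and averaged
vertically on a fixed 101-point FPR grid. The effect filter keeps a call
only if its effect reaches the (1−X) quantile of effects over *all* genes
in the dataset.

**Marker reproducibility.** Per gene and type: one-vs-rest MWU and AUC
(high in-type → AUC > 0.5); assignment by argmax AUC (lexicographic
tie-break); BH across genes on the assigned type's p-value. A gene is a
significant marker at (5% FDR, AUC ≥ T); reproducibility across a matched
pair is the fraction of genes significant in both that share an
assignment, swept over T ∈ {0.5, …, 0.95}. Cross-method concordance is the
disagreement fraction over genes significant under every method.

## Numerical and design notes

* **Discreteness of the Spearman p-value.** For genes detected in only a
  handful of cells, the t approximation is anticonservative: two near-empty
  genes sharing a single nonzero cell can reach ρ ≈ 0.2–0.3, whose t-based
  p is far smaller than the exact permutation probability of the overlap.
  On raw (unimputed) default NB simulations this produces a small residue
  of false-positive pairs (~0.02% of the family), all confined to the
  ultra-sparse end of the mean grid. The package keeps the stated
  approximation rather than silently filtering genes; interpret
  false-positive counts on raw data with this floor in mind.
* **Compositional library-size bias.** Because per-group expected profiles
  are renormalized to proportions, strong DE genes shift *every* gene's
  proportion in the affected group: with large DE factors and a
  heavy-tailed mean distribution, "null" genes in the grouped simulation
  carry a real compositional shift, and raw-data specificity can drop well
  below 1 − FDR. This mirrors the known CPM-normalization bias under
  strong asymmetric DE. The clean-null guarantees (FDR-level specificity)
  are therefore stated on the balanced two-group NB design; on grouped
  simulations the same quantity measures normalization bias plus
  imputation, not imputation alone.
* Degenerate inputs: zero library sizes raise errors naming the cell;
  k ≥ n_cells is rejected for smoothers; imputation thresholds outside
  [0,1] are rejected; permutation requires at least one gene above the
  screening threshold; ROC construction requires both truth classes.
* Problem sizes in the test-suite and acceptance runs match the stated
  study conditions where feasible (20 permutation-null datasets of
  2000×999; 500×1000 NB replicates; 2000×1000 calibration grids) and use
  smaller matrices for unit-level properties, chosen so the whole suite
  exercises every protocol end to end.

## Known limitations

* Imputer archetypes are reference mechanisms, not reimplementations of
  published tools; parameter-for-parameter agreement with those tools is
  out of scope (as are SAVER's shrinkage regression, autoencoders, and
  consensus ensembles — external tools can be attached via the registry).
* The permutation-null protocol inherits the screening threshold's
  imperfection: genes with weak true DE (p > 0.2 by chance) can enter the
  permuted set; this biases the protocol toward *under*-counting imputation
  artifacts, never toward inflating them.
* Real-data confounders (batch, cell size, stress response) are not
  simulated; published real-data results show higher and more variable
  false-positive rates than clean simulations, so synthetic results here
  should be read as lower bounds.
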