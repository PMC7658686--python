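# Methods

`metafunc` implements the downstream statistical stack of a metagenome-wide
functional association analysis: the data are a sample × function abundance
matrix (functions annotated as COGs — Clusters of Orthologous Groups), a map
of each function to its one-letter COG category and one of four broad
functional classes, and a table of per-sample clinical indices, for a cohort
divided into study groups (the motivating design is 15 healthy controls, 22
IBS-D, 15 depression and 13 comorbid patients). This note records the models,
the defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Containers and units

Abundances are non-negative; `unit="counts"` rows are unconstrained,
`unit="relative"` rows must sum to 1 (±1e-9). All inferential stages operate
on relative abundances because sequencing depth is a nuisance: closure makes
samples comparable but also makes the data compositional, so all
correlations here are correlations between proportions, not between absolute
abundances. A panel-restricted matrix is a sub-composition and deliberately
is *not* re-validated as relative (see `train_discriminator(features=...)`).
Zero-abundance (constant) functions are retained through I/O but excluded
from testing and correlation with a warning — their statistics are
undefined.

## Synthetic cohorts

The generator draws, per sample, a latent log-abundance vector
`log a_j = mu_j + sigma * z_j (+ log fold if enriched)` with `mu_j ~
N(0, mu_sigma²)` fixed per cohort, closes `a` to proportions, and samples
counts multinomially at a fixed depth. Correlated blocks share a latent
factor: within a block, `z_j = sqrt(rho) u + sqrt(1-rho) e_j`, giving
pairwise latent correlation `rho`.

Defaults and rationale:

* `group_sizes=(15, 22, 15, 13)`, labels HC/IBS-D/DEP/COMO — the target
  study design.
* `n_functions=200`, `depth=100_000` — large enough that multinomial
  (compositional) noise is small relative to biological noise for a typical
  function (expected count ≈ depth/n_functions ≈ 500), small enough that
  every test runs in seconds. Real COG profiles are an order of magnitude
  wider (~4,600 functions) and deeper; the statistics tested here do not
  depend on that scale, only their multiple-testing resolution does (see
  below).
* `mu_sigma=1.0` — about a 10-fold 95%-range in base abundance across
  functions.
* `sample_sigma=0.7` — per-sample biological variability of a function on
  the log scale (CV ≈ 80%), in the range seen for gut-microbiome functional
  modules.
* Planted enrichments multiply one group's abundance by a fold factor
  before closure. The recorded truth stores the closed expected proportions
  per group (`E[a] = exp(mu + log fold + sigma²/2)`, closed), so expected
  group-mean ratios can be recomputed exactly from the truth file.
* Clinical links: the index is `sign * s * z + sqrt(1-s²) * eps`, where `z`
  is the linked function's relative abundance rank-transformed and
  standardized **within each study group**. `s` is therefore the target
  *within-group* Spearman correlation — the scale on which biomarker
  selection screens clinical links. Cohort-wide ranks would be compressed
  inside an enriched group and would attenuate the planted strength exactly
  where it is measured.

What the generator does *not* emulate: annotation error, taxonomic
structure behind functions, depth variation between samples,
zero-inflation beyond multinomial sampling, and negatively correlated
blocks. Passing tests show the statistical machinery is correct and
calibrated under a clean compositional log-normal model; they do not show
robustness to those real-data features.

## Clustering (PCA + PAM)

PCA is the standard column-centered eigendecomposition (via SVD). PAM is
implemented directly: greedy BUILD seeding, then best-improvement SWAP
until no medoid/non-medoid exchange lowers the total dissimilarity, ties
broken on the lexicographically smallest (medoid, candidate) pair so the
result is deterministic; the `seed` argument exists only for interface
uniformity. By default PAM runs on Euclidean distances over the leading
principal components retaining ≥95% of variance (`use_pca=False` switches
to the raw profile). `k` defaults to 3 — the number of functional clusters
the motivating study reports — with `silhouette_scan` available for k=2..8.

PAM is a 1-swap local search: on well-separated instances it attains the
globally optimal medoid set (verified against exhaustive enumeration for
n ≤ 8), but on unstructured instances a 1-swap-optimal solution need not be
global — the test suite checks exactly these two properties separately.

## Differential abundance

Per function, the one-way ANOVA F statistic is referred to its permutation
null: group labels are shuffled, identically across all functions within a
randomization (preserving inter-function dependence), and in sampled mode
`p = (b+1)/(B+1)` where `b` counts null F ≥ observed (never zero by
construction). Exhaustive mode enumerates all distinct assignments of the
label multiset (refused above 10⁵ assignments) and reports the exact
proportion attaining the observed F, identity included — on two groups of
three with complete separation this yields p = 2/20 = 0.1. Constant
functions are flagged with p = q = 1. BH-FDR (statsmodels step-up) runs
across the tested functions. Pairwise contrasts use the two-sided Wilcoxon
rank-sum test, exact when the pooled sample is small (≤50) and tie-free,
normal approximation with tie correction otherwise; all-tied input reports
p = 1.

A resolution caveat that matters at desk scale: a permutation p can never
be smaller than 1/(B+1), while the BH threshold for the smallest p among m
tests is 0.05/m. Whenever `(B+1) < m/0.05`, no discovery is possible at
q < 0.05 regardless of effect size. Scripts therefore pick B compatibly
with m (e.g. B = 1999 for m = 200), and the all-null FDR simulation is
conservative for the same reason.

## Co-occurrence networks and complexity

Per study group, Spearman correlations (average ranks for ties) are
computed between all function pairs over that group's samples; the
permutation null shuffles the sample order of one member of each pair (one
shared shuffle per randomization), p = (b+1)/(B+1) on |r|, BH over the
strict upper triangle. An edge requires q < 0.05 and r ≥ 0.8 (positive) or
r ≤ −0.8 (negative); isolated nodes are kept unless pruned. SparCC-style
compositional correction is out of scope; thresholds are on plain Spearman
r.

Category summaries are pair-normalized edge densities: **internal
complexity** of category c = within-c edges / C(n_c, 2) (zero when n_c <
2); **interaction complexity** of (c1, c2) = cross edges / (n_c1 · n_c2),
symmetric, with the diagonal reporting internal complexity. The **active
index** of a node is degree/(|nodes|−1) ∈ [0, 1]. These densities are this
package's concrete definitions of the category-complexity summaries; they
are bounded, relabeling-invariant, and comparable across categories of
different size.

## Biomarker selection and discrimination

A function enters the panel for group g when (1) its permutation-ANOVA
p < 0.01 (raw permutation p, 1000 randomizations by convention), (2) its
Spearman correlation with at least one configured clinical index, computed
over group g's samples only, has p < 0.05 — Bonferroni-corrected across
the group's index set by default (`correction="none"` gives the uncorrected
variant; both conventions appear in practice), and (3) its group-mean
relative abundance is maximal in g. Selection is deterministic and its
evidence (best index, r, raw and adjusted p, mean rank) is recorded.

The classifier is a one-vs-rest random forest (500 trees, √m features per
split — standard defaults, configurable) under stratified five-fold CV,
repeated with re-randomized folds (default 100 repeats); the headline
number is the mean held-out AUC over all fold-repeats, and the ROC band is
the min/mean/max held-out TPR per FPR grid point.

Selecting the panel on the full cohort and cross-validating only the
classifier is the protocol this pipeline reproduces by default; it leaks
the selection step. `audit_selection_leakage` re-runs selection inside
each training fold (an empty fold-panel scores 0.5, no information) and
reports both AUCs so the optimism is measurable; on all-null data the
audited AUC stays near 0.5 while the unaudited one need not.

## Clinical statistics

Pearson χ² without continuity correction (the convention matching the
motivating cohort's printed sex statistic, 1.792 on [[10,10,9,7],
[5,12,6,6]]; a Yates flag exists), classical one-way ANOVA, and mean ± SEM
(sample SD/√n, undefined for n = 1) summaries. Spearman screens of any
feature table against clinical indices use pairwise-complete observations
(never imputed), exact rank-permutation p for tie-free n ≤ 7 and the t
approximation otherwise; pairs with < 4 complete observations are reported
as not assessable.

## Reproducibility

Every randomized stage takes an explicit integer seed; identical seeds give
bit-identical outputs, including written TSVs. The pipeline driver records
versions, parameters, seeds and per-stage row counts in a YAML manifest.
The test suite and the acceptance script use deliberately modest problem
sizes (stated above and in the scripts themselves) chosen so the full
validation runs in minutes; all conclusions they support are about
correctness and calibration, not about field-scale effect sizes.

## Known limitations

* Spearman-on-proportions ignores compositional coupling; strong negative
  closure-induced correlation can create edges with no ecological meaning.
* Permutation/BH resolution bounds discoveries at small B (see above).
* The complexity indices are edge-density summaries; they are not claimed
  to equal any unpublished variant of such indices.
* PAM returns a 1-swap-optimal solution, not a certified global optimum.
* The leakage audit assigns 0.5 to folds with empty panels, which biases
  the audited AUC toward 0.5 when selection is very sparse.
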