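# Methods

This note records the statistical model behind `fcmodules`, the
numerical choices made where the procedure is underdetermined, what the
synthetic generators do and do not emulate, and known limitations.

## Preprocessing

Input matrices are genes × samples with unique string identifiers on
both axes and no missing values. The fixed preprocessing order is
quantile normalization between arrays → gene (row) centering →
per-array (column) scaling and centering. Sample standard deviations
use the unbiased n − 1 denominator everywhere, which is also why the
covariance eigenvalues and the whitening scale carry the g − 1 factor.

Quantile-normalization ties: the reference distribution is the vector
of row means of the column-sorted matrix; tied values within a column
receive the average of the reference values spanning the tied sorted
positions. This makes the map purely rank-based and idempotent. Two
normalization modes exist: fresh (reference computed from the matrix at
hand, the default — each study is processed independently) and
reference-distribution (a stored sorted reference is supplied), for
projecting new studies against a frozen compendium distribution.

## Representative compendium

Distances between arrays are 1 − ρ (Spearman by default; Pearson
offered). Average-linkage agglomeration is delegated to
`scipy.cluster.hierarchy`. The cut height comes from a k-nearest-
neighbor knee plot: each sample's distance to its k-th nearest
neighbor, sorted ascending, with the knee defined as the point of
maximum perpendicular distance from the chord joining the curve's
endpoints. A visual knee read is inherently subjective; the
chord-deviation rule was chosen because it is deterministic, and a
manual height override is always available (0.3 with k ∈ {4, 5} is the
recorded default for large heterogeneous compendia). A near-linear
curve (maximum deviation < 1e-9) raises rather than returning an
arbitrary height. Clusters below `min_size` (default 5) are dropped;
each survivor is represented by its medoid — the member minimizing
summed distance to the rest — with ties broken to the smallest sample
index. Cluster labels are numbered by first-occurring sample index so
results are independent of library internals.

## Whitening and component count

X = U D Vᵀ via `numpy.linalg.svd`; e_i = d_ii²/(g − 1);
Y = √(g − 1) · U[:, :n], so YᵀY = (g − 1) I exactly. Rank-deficient
inputs keep their trailing zero singular values.

Parallel analysis simulates i.i.d. standard-normal matrices of the same
shape (un-standardized; whether to standardize simulated matrices is an
open choice and N(0, 1) is the recorded assumption), computes their
eigenvalues with the identical g − 1 divisor so bias and observation
are commensurable, and takes the median (Horn) or 95th percentile
(Glorfeld) per index as the bias. The retention rule is
e_i − bias_i > 1 — stricter than the conventional e_i > bias_i, which
remains available as `rule="above_bias"`. Simulation eigenvalues are
computed by SVD of each simulated matrix, not by a Marchenko–Pastur
approximation. The default simulation count is 5000; tests and the
acceptance script use 60 simulations, which is ample for the strongly
separated spectra they construct (the planted eigenvalues sit an order
of magnitude above the bias).

## ICA

Two backends unmix Y = S A:

- **logcosh** (default): symmetric fixed-point negentropy maximization
  with the log cosh contrast — fast, deterministic given the seed, and
  well suited to the heavy-tailed loading distributions of expression
  data. Per-component negentropy is the classic approximation
  (E[log cosh s] − E[log cosh ν])², ν standard normal.
- **proden**: a tilted-Gaussian contrast in which each source's density
  is estimated nonparametrically each iteration — a kernel-smoothed
  histogram on a grid (`grid_points`, default 2000) — and the
  fixed-point update uses the first two derivatives of the estimated
  tilt g(s) = log f̂(s) − log φ(s). Per-component negentropy is the
  mean tilt E[ĝ(s)]. The `order` parameter (default 11) is an opaque
  robustness knob controlling the minimum smoother width in grid bins.

Negentropy scores are each backend's own contrast and are comparable
only within a backend; `select_best` refuses mixed-backend lists.
Convergence is the maximum change in unmixing directions < `tol`
(default 1e-6, capped at `max_iter` = 8000 iterations); non-converged
runs are returned flagged, with a warning, never silently. Random
initialization is a Haar-orthogonal matrix from the seeded generator;
a batch of runs uses seeds base_seed + run index. Source columns are
re-standardized to exactly zero mean and unit sample SD, with the
mixing matrix recomputed so Y = S A holds to machine precision.

Canonical form: columns are sign-flipped to nonnegative sample skewness
(the corresponding rows of A flip too), then sorted by decreasing
skewness with ties keeping original order. The nonnegative-skewness
sign convention is a deliberate choice where only "order by skewness"
is determined.

## Cross-run alignment

r⁻ = (1 − ρ)/2, r⁺ = (1 + ρ)/2, ℂ = min(r⁺, r⁻) over pairwise Pearson
correlations; the assignment minimizing total cost is found with
`scipy.optimize.linear_sum_assignment` (exact Hungarian, not greedy).
The signed permutation carries +1 on an assigned cell when r⁻ < r⁺ and
−1 when r⁻ ≥ r⁺, so an exactly uncorrelated tie (ρ = 0) gets −1 — the
branch is applied as written. Aligned correlations are therefore always
nonnegative. Multiple cost-optimal matchings are resolved by the
algorithm's deterministic scan order.

Stability over repeated runs is summarized per component as mean, SEM
(over runs, per component) and max of aligned correlations. The
resampling variant draws columns without replacement (size defaults to
the full width, "similar-sized"), whitens with the reference component
count fixed, runs ICA `runs_each` times per resample (default 10,
spec'd 50 resamples), keeps the highest-negentropy solution and aligns
it to the reference.

## Annotation

Active genes are loadings strictly beyond mean ± z·SD (z = 3), with
mean and SD taken from the component's own loading column, not pooled.
Enrichment is a hypergeometric upper tail P(X ≥ overlap) per
module–signature pair with BH correction across all pairs; the universe
must be supplied explicitly (normally the loading matrix's gene list).
BH supports a family size N larger than the number of p-values passed,
for adjusting a subset of a known family. GO-graph-aware testing is out
of scope; flat over-representation on GMT sets is the provided
mechanism, and slim collapsing is expected to happen through an
explicit user-supplied term→slim mapping upstream.

## FC space

Projection is Q_FC = Sᵀ Q on the gene-ID intersection; loading genes
missing from the query are dropped, not zero-imputed, and the coverage
fraction is reported with a hard floor (default 90%). Raw loadings are
the default projection basis; unit-norm columns are an explicit flag
(both conventions appear in practice and the package takes no side —
the flag is recorded in the projection object). Correlations in FC
space are Pearson on score vectors. Neighbor retention keeps reference
samples correlating > `min_cor` (default 0.95) with at least
⌈min_frac · group size⌉ group members; the inequality is strict, so
`min_cor = 1.0` retains nothing. Tissue fingerprints keep one medoid
per label under 1 − Pearson; label pairs are summarized by the median
and SD of all cross-sample correlations, and queries are annotated with
the label of highest median correlation.

## Evaluation

Differential FC testing uses Welch's two-sample t-test by default
(`equal_var=True` restores Student's; "unpaired t-test" alone does not
pin the variance assumption, and Welch is the safer default), BH
over an explicit family size. Clustering quality: purity (fraction
matching the cluster-majority mega-class, ties to the lower-indexed
class and flagged) and per-cluster Gini impurity 1 − Σ f². Cophenetic
comparison is the Pearson correlation of the two cophenetic-distance
vectors.

Max-vote classification trains one-vs-one linear SVMs
(`sklearn.svm.SVC`, C = 1 — unstated in the sources, standard default)
inside stratified k-fold cross-validation (default 30 folds, 3 runs);
vote ties are indeterminable calls, never forced; per-class sensitivity
divides correct calls by determinable calls of that class; counts are
averaged over runs. A class pair missing from a training fold is
skipped with a warning.

McNemar's comparison uses the continuity-corrected statistic
(|b − c| − 1)²/(b + c) with a χ²₁ tail; perfect agreement yields the
verdict "identical" with an undefined statistic rather than a fake
zero. Binary metrics report undefined PPV/NPV as None, never 0.

The subsampling harness holds out fixed test sizes per run, subsamples
the remaining pools at each fraction (defaults 5–80% plus 1.0; 200
repeats, except fraction 1.0 which is deterministic given the split and
runs once), trains one classifier per feature space, and aggregates
within-run means into across-run mean ± SD, excluding undefined values
from averages but reporting their counts. Per-run seeds are
base + run index; per-repeat seeds are run_seed·1000 + repeat index —
arbitrary but fixed, making the whole experiment bit-reproducible. The
number of runs is a required parameter of the CLI (sources disagree on
10 vs 100; the library default is 10).

## Synthetic data

`gen_mixture` draws standardized independent super-Gaussian sources
(Laplace default — provably positive excess kurtosis; an exponential
and a sparse Gaussian-mixture family stress asymmetric and multimodal
densities), mixes them with a Haar-orthogonal or standard-normal
matrix, and optionally adds Gaussian noise. `gen_two_class_study`
plants a low-rank group signal: sample expression is S·w + gene noise,
with group B's mean weight shifted by `effect_size` on chosen
components, optionally plus per-batch gene-space intercepts. Defaults
(2000 genes, 20 per group, 5 components, unit gene noise) are sized so
planted effects of 2 SD are detectable but not trivial.

What the generators do **not** emulate: probe-level noise, saturation,
intensity-dependent variance, correlated source loadings, or the
long-tailed cluster-size distribution of real compendia. Passing tests
demonstrate correctness of the algorithms under the stated generative
model — identifiable super-Gaussian sources — not performance on any
particular real platform.

The Amari index used as the recovery oracle is the normalized form in
[0, 1], zero exactly on scaled signed permutations. With X = S A (genes
as rows), the per-observation mixing is Aᵀ, so recovery checks compare
the composed unmixing against Aᵀ.

## Problem sizes

The default test and acceptance workloads use 2000-gene, 5-component
mixtures for recovery (10 seeds), 500 × 40 matrices for parallel
analysis (60 simulations, 10 seeds, both quantiles), exhaustive
signed-permutation verification up to n = 6 against brute-force
matching, and 50 null two-class studies for calibration — sizes at
which every property is sharply decided while the whole suite runs in
seconds.

## Known limitations

- Negentropy scores are contrast-specific; absolute values are not
  comparable across backends or to other software.
- The proden backend's density estimate is histogram-based; for very
  small gene counts (< ~500) the logcosh backend is more reliable.
- Parallel analysis assumes approximately standardized columns; run it
  on preprocessed matrices.
- The knee rule needs a genuinely convex k-NN curve; heterogeneous
  compendia without scale separation require a manual height.
- `maxvote_classify` re-trains all O(k²) pairwise SVMs per fold; very
  large class counts will be slow.
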