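# Methods

## Model and procedure

`fmskit` operates on a samples × taxa matrix of relative abundances.  Rows
are closed to percentages (sum 100); zero-variance taxa are removed before
any supervised step.  The pipeline is:

1. **Merging.**  All pairs of current columns are scored by pairwise LDA.
   For a pair (u, v) the 2×2 between- and within-class scatter matrices are
   submatrices of the full scatters, so one pass over the data prices every
   pair; the 2×2 generalized eigenproblem is solved in closed form.  The
   pair maximizing the merging value F_new·|r|/√(F_u·F_v) is replaced by its
   best linear combination; member lists concatenate and weights multiply
   through and are renormalized to unit L2 norm.  Ties break to the
   lexicographically first pair, so the loop is deterministic.
2. **Degree selection.**  The merge count is chosen by proportional
   (stratified) 5-fold cross-validation: within each fold the merge path is
   grown incrementally and a fresh classifier is trained at every degree on
   the fold's merged columns and scored on the held-out fold by mean
   per-class error.  Equal-error ties go to the largest merge degree (fewest
   dimensions).
3. **Per-combination refit.**  Each combination with ≥ 2 members gets its
   weights re-estimated by LDA restricted to its member taxa, keeping the
   direction with the highest projected Fisher score.
4. **Deletion.**  Surviving taxa are ranked ascending by |weight| ×
   combination Fisher score and deleted one by one; the deletion count is
   again chosen by stratified 5-fold CV, with equal-error ties resolved
   toward fewer dimensions, then fewer features.  Each fold re-learns its
   own merge path, refit and ranking, so the curve is honest about the
   whole procedure.  Emptied combinations are dropped; remaining weights
   are renormalized.
5. **Noisy branch.**  If the best single taxon carries less than
   `noise_threshold` (default 0.03) bits of mutual information about the
   class — features discretized at midpoints of per-class medians — Fisher
   ranking is considered unreliable: deletion ranks by mutual information
   instead, and both degree selections switch from the plain CV minimum to
   an error-plus-penalty criterion.  Among the m = ⌈log₂ N⌉ lowest-error
   curve points (N = dimension after preprocessing), the penalty weight is
   λ = (error range)/(dimension range) and the chosen degree minimizes
   error + λ·dimension; exact ties re-run the rule once with m grown by the
   tie count − 1, and residual ties take the lowest dimension.

The frozen model stores the preprocessing state, every combination's member
indices and weights, the merge log and deletion order; `transform` is a
sparse linear map, so applying the model to held-out data reproduces the
training-time columns exactly.

### LDA engine

The within-class scatter is S_W = Σₖ Σ_{y∈k}(y−mₖ)(y−mₖ)ᵀ/(N−K).  Two
between-class conventions are supported: the default weights class k by
(nₖ−1)/(K−1); `scatter_convention="standard"` uses nₖ/(K−1), which is the
quadratic form whose ratio with S_W is exactly the Fisher statistic of a
projection.  For two classes both produce the same directions (the between
matrix is rank one either way); projected Fisher scores are always
evaluated with the standard numerator.  Singular S_W is repaired by adding
eps·I repeatedly until the smallest eigenvalue clears a scale-aware
threshold, 1e-10·(1 + trace/d); eps defaults to 1e-6 × the mean diagonal of
S_W with an absolute floor of 1e-12.  The eigenproblem is solved by
Cholesky whitening of the regularized S_W, and eigenvector signs are fixed
by making the first significant component positive, so all directions are
deterministic.

### Classifiers and evaluation

All model selection uses proportional k-fold assignment (within-class
shuffle, round-robin deal; every fold holds each class's count within ±1 of
nₖ/k) and the mean per-class error — the unweighted average over classes of
the fraction of that class misclassified, which is insensitive to class
imbalance.  Classifiers satisfy a minimal fit/predict contract:

* **kNN** — Euclidean distances on features standardized by training
  statistics, votes weighted 1/d²; an exact-zero distance short-circuits to
  that neighbour's label; vote ties go to the class appearing first in the
  training labels.  k is fixed (default 1) or selected over 1..10 by CV.
* **SVM** — RBF kernel exp(−‖x−y‖²/c) via scikit-learn (gamma = 1/c).  The
  kernel width defaults to the scale heuristic; `c="cv"` selects it over a
  geometric grid by stratified CV once at fit time rather than inside every
  learning-curve point, where a nested grid search would multiply the
  classifier fits without changing the curve's shape.
* **Three classes** — a cascade: the designated control class versus the
  rest, then the two remaining classes.  (One-vs-all scoring is not
  implemented; the cascade is the default and only three-class scheme.)
* **Imbalanced two classes** — the majority class is k-means-clustered
  (deterministic first-k seeding, Lloyd iterations, empty clusters keep
  their previous mean) into 3 subgroups; each subgroup plus the minority
  class trains one voter; majority vote decides.  With 3 voters and 2
  classes ties are impossible.

### Baselines

Four standard feature rankers are included for comparison: mRMR (quotient
criterion on presence/absence data, with an ε = 1e-12 guard on the
redundancy denominator), information gain (≡ mutual information with the
class, base 2), the χ² statistic of the 2×K presence/class table (cells
with zero expected count contribute nothing), and the Kruskal–Wallis H test
on the raw abundances (scipy's tie-corrected statistic; constant features
score 0).  A helper selects the top-q features by the same CV error
criterion used for the main pipeline.

## Synthetic data generator

The generator emulates a genus-level 16S survey: ~50–150 taxa, tens of
samples per class, blocks of strongly correlated informative taxa, and many
sparse class-independent taxa.  Construction is lognormal: informative taxa
get per-feature baselines (log-SD 1 across taxa), a within-class log-SD of
0.4, a shared group latent scaled to the requested within-group correlation,
and centered class offsets with adjacent classes `effect_size` within-class
SDs apart.  Three choices matter and are deliberate:

* **Within-class log-SD 0.4.**  The exponential map attenuates correlation
  (a log-scale 0.95 can land well under 0.9 on the abundance scale at
  σ = 1); at σ = 0.4 the requested group correlation survives the map and
  the closure, which is the contract the rest of the package relies on.
* **Balanced contrasts.**  Class offsets are assigned to groups by cyclic
  rotation (a Latin square), so the per-class total informative load is
  near-constant.  Relative abundances carry only compositional information:
  signal placed in the total load is removed by the closure, so an
  unbalanced generator would silently deliver a fraction of its nominal
  effect size.
* **Rare noise taxa.**  Class-independent taxa with 60% structural zeros
  are the rare tail of a survey; their baselines sit 1.5 log-units below
  the informative taxa.  This is also what keeps row totals — and hence
  closure noise — governed by the abundant taxa.

What the generator does **not** emulate: phylogenetic correlation
structure, integer read counts and sequencing-depth variation, batch
effects, and taxa whose class association is in presence/absence rather
than abundance.  Tests passing on these fixtures show that the machinery
recovers planted redundancy/signal structure under closure and sparsity;
they do not certify performance on real surveys, where effect sizes are
smaller and noise is not independent across taxa.

## Numerical choices and edge cases

* Fisher statistic with zero within-class variance and positive
  between-class variance returns +inf (it must outrank every finite
  score); inside merging values infinities are capped at 1e30 so ratios
  stay ordered.
* A pair whose Fisher geometric mean is exactly zero cannot divide; it is
  ranked at 1e-12 × the merged Fisher score so purely uninformative
  features merge last instead of crashing the loop.
* Pearson correlations between merged columns are computed between the
  *current* combined columns (the only reading under which the merging
  value stays defined after the first merge); constant columns get r = 0.
* Mutual information uses plug-in (maximum-likelihood) probabilities and
  base-2 logarithms throughout — the 0.03 noisy threshold is in bits and
  is configurable, as is the noisy summary statistic (max per-feature MI by
  default: if even the best feature is uninformative, the dataset is
  noisy).
* Zero-variance removal uses exact equality on the unbiased sample
  variance: constant columns are exactly constant after percentage
  conversion, so no epsilon is wanted.
* Deletion renormalizes the surviving weights of a combination (the
  alternative — keeping stale weights — would make `transform` depend on
  deleted columns).

## Known limitations

* **The merging value is unstable against near-null features.**  For a pair
  of one strong feature (Fisher F_i) and one class-independent feature
  (F_j ~ F(1, n−2) under the null), the merged Fisher is ≥ F_i, so the
  merging value scales like √(F_i/F_j)·|r| — and small-F_j features are
  common (P(F_j < 0.05) ≈ 0.18 under the null).  Early merges therefore
  often absorb a near-null taxon into a strong combination with a tiny
  weight, ahead of genuinely redundant pairs.  The redundancy bias of the
  criterion is real but only dominates among comparably informative
  features; the Step-8 refit and the deletion stage are what ultimately
  remove the absorbed noise.  This is a property of the criterion itself,
  not of its implementation.
* CV learning curves select the degree at the observed error minimum over
  many candidate degrees, so the selected CV error is optimistically
  biased; held-out evaluation (the `evaluate` subcommand, or the split
  protocol used in the acceptance script) is the unbiased measurement.
* With the (nₖ−1) between-class weighting and K ≥ 3, the leading LDA
  direction can differ slightly from the projected-Fisher maximizer; the
  refit step compensates by choosing the direction with the highest
  projected Fisher among the eigendirections.
* Problem sizes: the shipped fixtures use 40–150 samples and 18–52 taxa,
  and the test suite and acceptance script complete in a few minutes on a
  single core.  The merge loop costs O(n·d³) per full path and the CV
  curves a classifier fit per fold per degree, so tables with thousands of
  taxa would need a capped merge degree.
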