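# Methods

## Problem and model

`ampdepth` quantifies how much amplicon sequencing depth a supervised
classification task actually needs.  The input is a labelled ASV table —
samples × amplicon sequence variants, non-negative integer read counts, one
categorical class per sample (a biotic-index category, a geographic origin, a
production phase, ...).  The procedure:

1. **Filtering.** ASVs with fewer than 50 reads summed over all samples are
   dropped (uninformative noise), then samples with fewer than 15,000 reads
   are dropped.  The ASV threshold is a dataset-wide total, not a per-sample
   minimum; a per-sample reading would remove most of the feature space.
   Filters run once, on the full-depth table; rarefied tables inherit the
   retained ASV set so the feature space — and hence the `mtry` grid — is
   constant across depth levels.
2. **Full model.** The count matrix is converted to relative abundances
   (each count divided by its sample total) so residual depth differences
   cannot act as a predictive signal.  A grid of random forests is trained:
   7 values of `mtry` (the `floor(sqrt(p))` default plus offsets −3..+3,
   clipped to `[1, p]` and deduplicated) × 3 repeat seeds = 21 models, each
   with 6000 trees by default.  Every model is scored by its out-of-bag
   (OOB) error — each sample predicted only by trees whose bootstrap did not
   contain it, a drop-in for N-fold cross-validation — and by Cohen's kappa
   computed on the OOB confusion.
3. **Depth ladder.** The table is rarefied (uniform subsampling of reads
   without replacement, i.e. a multivariate-hypergeometric draw per sample)
   to a ladder of depths: the shallowest retained sample's depth first, then
   12,500, 10,000, 7,500, 5,000, 2,500, 1,000, 500, 400, 300, 200, 100, 50.
   One rarefied table is drawn per level; all 21 models at a level see the
   same table.  The same 21-model grid is retrained at every level.
4. **Decision.** Kappa is banded: *almost perfect* (> 0.8), *moderate*
   (0.6–0.8, both ends inclusive), *poor* (< 0.6).  The full model's band is
   the benchmark.  Walking the ladder from deepest to shallowest, the
   minimum sufficient depth is the last level of the initial contiguous run
   of levels whose band is at least the benchmark band; if even the deepest
   level fails, the result is "not reached".

### Gating choices

A level is summarized by the **median kappa** of its 21 models (robust to
the grid's worst configurations) and by the mean OOB error / mean accuracy.
The band gate uses the median by default; `gate="best"` bands the single
best model (max kappa, ties broken by lower OOB error then lower `mtry`)
instead, since an argument can be made for either summary and the choice is
left explicit.  Accuracy is reported at every level but never gates: there
is no principled accuracy-drop threshold, though the per-level table makes
any drop visible.

### Ladder cap

Datasets are comparable only if their ladders start near the same depth.
The first level is therefore capped (default 15,000 reads), but the cap
engages only when the shallowest sample exceeds it by more than 1.5× —
a dataset whose minimum sits a few percent above the cap keeps its own
minimum as the first level, while a dataset sequenced to twice the cap is
pulled down to it.

## Saturation diagnostics

Bias-corrected Chao1, `S_obs + f1(f1−1) / (2(f2+1))`, estimates the total
richness from singleton/doubleton counts and serves as the 100%-coverage
reference; coverage is `100 · S_obs / Chao1`.  Coverage is computed on the
pooled (dataset-level) abundance vector, per ladder level.  Expected
rarefaction curves use the exact hypergeometric formula
`E[S_d] = Σ_a [1 − C(N−n_a, d)/C(N, d)]`, evaluated through log-gamma to
avoid overflow, with a Monte-Carlo cross-check available.

Note that after the ≥50-reads ASV filter the pooled vector often has no
singletons left, so dataset-level coverage of a filtered table is near
100% by construction; coverage differences are informative *along the
ladder*, where rarefaction reintroduces rare counts.

## Separability diagnostics

Why do some tasks hold their performance band at 50 reads while others need
5000?  The package computes four per-dataset diagnostics:

* **Gini coefficient of class sizes** — `Σ_ij |x_i − x_j| / (2 n Σx)` over
  ordered pairs; 0 for perfect balance.  Measures training-data imbalance.
* **Per-feature CV** — for each ASV, the standard deviation (n−1) of its
  class-mean relative abundances divided by their grand mean; features with
  grand mean 0 are excluded and counted.  High-CV features are
  class-discriminating; a dataset rich in them keeps its signal when reads
  are scarce.
* **Shared-feature fractions** — an ASV is present in a class when its
  pooled count there is ≥ 1 (configurable); the fractions present in all
  classes / exclusive to one are computed twice, counting ASVs and
  weighting by reads, since "sequences common to all classes" is ambiguous
  between the two readings.
* **Ordination ellipse overlap** — Bray–Curtis dissimilarities on relative
  abundances, embedded by non-metric MDS (8 random restarts, best stress
  kept, seeded); each class gets a normal-theory 95% confidence ellipse
  (chi-square radius on its 2-D mean and covariance); pairwise overlap is a
  seeded Monte-Carlo estimate of the mutual area fraction, averaged over
  both directions.  A degenerate (collinear) class covariance is inflated
  by `1e-6 ×` the squared coordinate scale and flagged rather than
  rejected.

Hard class boundaries ⇒ high CV, low shared fraction, low ellipse overlap ⇒
few reads suffice.  This chain is exercised as a testable property, not just
described.

## Synthetic communities

The generator emulates the *shape* of real benthic amplicon surveys without
claiming fidelity to any one of them: a log-normal expected-abundance
profile over `n_background` shared ASVs plus `n_specific` ASVs per class
whose expected relative abundance is multiplied by `effect_size` in their
home class (then renormalized); per-sample compositions are Dirichlet draws
with total concentration `overdispersion` (smaller = noisier); counts are
multinomial at a per-sample depth drawn uniformly from `depth_range`.

Defaults: 3 classes of (25, 24, 27) samples, 2800 + 3×80 = 3040 ASVs,
depths 15,000–40,000, `effect_size = 8`, `overdispersion = 150`,
log-normal(0, 1.5) base profile — a 76-sample survey with a clearly
learnable class signal.  `effect_size = 1` collapses the design to an exact
null.  Random streams are keyed by `(seed, sample index)`, so extending a
design preserves previously generated samples bit-for-bit.

What the generator does *not* emulate: taxonomic correlation structure,
sample-to-sample depth correlation with class, sparsity patterns of real
sequencing error, or compositional gradients within a class.  Tests passing
on these communities therefore demonstrate the correctness of the
procedure's mechanics and its qualitative parameter response (harder
boundaries ⇒ shallower sufficient depth), not quantitative transfer of any
specific minimum-depth number to field data.

## Numerical and implementation choices

* Random forests are scikit-learn's `RandomForestClassifier`
  (`max_features = mtry`, `oob_score=True`); the OOB class-probability
  matrix provides per-sample OOB predictions.  Samples with zero OOB trees
  (possible at very small forests) are excluded from scoring with a
  warning.
* Cohen's kappa is computed from first principles
  (`(p_o − p_e)/(1 − p_e)`); the both-vectors-constant-and-equal case is
  defined as 1.  The implementation is cross-checked against an independent
  library routine in the test suite.
* Hypergeometric sampling uses numpy's `multivariate_hypergeometric`
  (sequential conditional per-ASV draws, O(ASVs) per sample); its
  distributional identity with uniform subset draws is asserted against
  closed-form moments.
* Seeds: a master seed fans out via SHA-256 over `(stage, level, ...)` keys
  to sub-seeds below 2³¹, so stages are independently reproducible and the
  whole pipeline is a pure function of (input, config, seed).  Re-running a
  pipeline writes byte-identical TSV/JSON outputs.
* Test and example runs use 60–300 trees rather than the 6000-tree
  production default; on the synthetic communities, band decisions
  stabilize far below 6000 trees, and the default is kept for fidelity to
  survey-scale practice, not because results here require it.

## Known limitations

* The minimum-depth decision inherits the variance of a single rarefied
  table per level (re-rarefaction per model is deliberately not the
  default, keeping the 21 models comparable); near a band edge the decision
  can flip between master seeds.
* NMDS stress is not checked against a quality threshold; a poor 2-D
  embedding will silently degrade the ellipse-overlap diagnostic.
* The ellipse overlap is an area fraction of normal-theory ellipses, not a
  formal multivariate test (PERMANOVA is out of scope).
* BIOM input is not supported; matrices are TSV (ASVs as rows by default,
  `--samples-as-rows` to transpose).
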