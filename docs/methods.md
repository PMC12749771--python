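# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the design decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The classifier

One transformer block with single-head self-attention over the patches of a
slide bag, followed by mean pooling and a two-way linear head with softmax.
With patches as rows of `x` (N_x × d):

- `K = xW_K`, `Q = xW_Q`, `V = xW_V`, projections `d → a` (defaults
  d = 768, a = 64);
- scores `S = K Qᵀ` (N_x × N_x); the softmax is applied along the second
  (attended) index so each row of `A` is a probability distribution. The
  row/column orientation of this construction is not canonical; this
  convention is fixed here and recorded in the hyperparameters.
- **No 1/√a score scaling** by default. The unscaled product is implemented
  literally; `MILHyperparams.scale_scores` enables conventional scaling.
- `A V` has width `a`, so the post-attention MLP maps `a → m → d`
  (m = 1024 by default) before the residual `x + MLP(AV)` — without this
  the residual sum would be dimensionally inconsistent.
- Layer normalisation is applied **after** each residual addition
  (post-norm). Pre-norm is the other defensible reading of "attention, then
  layer normalisation, then MLP"; post-norm was chosen and is used
  consistently in both sub-layers.
- Both MLPs are two fully-connected layers with ReLU between; no dropout.
- Slide probability: mean-pool the rows of the block output, linear head
  `d → 2`, softmax. No positional embedding, hence exact permutation
  invariance of the slide probability (tested to < 1e-6).

Training: Adam (β = 0.9/0.999, ε = 1e-8) with L2-coupled weight decay
5e-3, cross-entropy loss, batch size one bag, 80 epochs, learning rate
1e-4. Class imbalance is handled by a weighted sampler: each epoch draws
`n_train` bags with replacement, with probability inversely proportional to
class frequency. Initialisation is seeded uniform fan-in scaling
(`U(±1/√fan_in)`) with zero biases; the seed is part of the hyperparameters
and two runs with the same seed are bit-identical. The whole network is
numpy/float64 with hand-written reverse-mode gradients, checked in the test
suite against central finite differences (tolerance 1e-5) and against an
independent straight-line per-patch implementation of the four block
equations (1e-6).

Empty bags and feature-dimension mismatches raise typed errors; a training
set containing a single class is rejected.

## Patch importance

`W_i = (1/N_x) Σ_j log A_ij` with entries clamped at 1e-12 before the log
(softmax can underflow to exact zero). Two axis conventions are provided:

- `literal` (default): mean over the second index of a row-stochastic `A`.
  Because each row sums to one, Jensen's inequality bounds this by
  `log(1/N_x)` with equality at a uniform row — the literal statistic
  therefore measures how *uniformly* a patch distributes its outgoing
  attention.
- `received`: mean over the first index, i.e. the average log attention a
  patch *receives* from all queries. This is the convention that localises:
  on trained separable synthetic cohorts the top-10 received-attention
  patches are enriched for ground-truth signal patches in ≥ 80% of mutant
  test slides (the acceptance suite computes the rate), while the literal
  statistic is not expected to localise, for the Jensen reason above.

Top-k selection sorts by weight descending with ties broken by ascending
index; ranking is invariant to the 1/N_x factor. Heatmaps are rendered at
patch-grid (stride) resolution — the statistic is per-patch — with empty
cells flagged as missing and optional min-max normalisation.

## Evaluation statistics

- AUC is the tie-corrected Mann-Whitney probability (computed via ranks;
  the ROC curve itself comes from scikit-learn). A property test compares
  it against an O(n²) pairwise oracle.
- The "balanced" operating point maximises Youden's J = SEN + SPE − 1 over
  observed scores and their midpoints (a `min|SEN−SPE|` mode is
  selectable); the F1 threshold is a separate exhaustive scan. Ties take
  the lower threshold. Orientation is fixed: positive iff
  score ≥ threshold, score = P(mutant).
- DeLong 95% CIs use the structural-components variance estimator with a
  normal quantile, clipped to [0, 1]. Empirical coverage at n = 60 under a
  bi-normal model sits slightly below nominal (the normal approximation is
  anticonservative at this n); the acceptance suite measures it against a
  [0.92, 0.98] band.
- Permutation significance: `p = (1 + #{AUC_perm ≥ AUC_obs})/(n_perm + 1)`,
  one-sided, seeded; for cross-validated results the permutation is applied
  to the predictions pooled over all folds.
- Model comparisons over fold AUCs use the one-sided Welch (unequal
  variance) two-sample t-test; fold variances are not asserted equal. The
  degenerate zero-variance case returns 0.5/0/1 by the sign of the mean
  difference.
- Cross-validation folds are patient-level (all slides of a patient share a
  fold — slide-level splitting would leak patients) and stratified by the
  patient-level task label via a round-robin dealer that keeps both fold
  sizes and per-fold class counts within one of proportional.
- Fold-spread CIs (t-interval over per-fold AUCs) and DeLong CIs are both
  available; every report tags which method produced its interval.
- No multiple-testing adjustment is applied anywhere; reported p-values are
  per-task.

## Re-biopsy re-checking

Each patient's slides are replayed in biopsy order. The human count is the
1-based index of the first Pass slide (total slide count if none passes —
the real sequence simply ended). The AI count is the order of the first
slide on which a **truly mutant** gene is called positive at its threshold
(gene-matched "accurate" detection; a lenient any-positive mode is
selectable). Patients with no mutant gene, and mutant patients the model
never flags, fall back to the human count; the count convention for those
patients is not canonical, so both the capped counts and the raw
first-detection counts are kept in the result. The cap makes
`ai ≤ human` per patient and the reduction ratio nonnegative by
construction. Decision thresholds always come from training data (per fold,
or from the training cohort in the consecutive mode) and are never refit on
the streams being scored. The paired one-sided t-test compares human vs AI
counts per patient. Every result carries an explicit caveat string: the
analysis is an optimistic upper bound, since ground-truth mutation status
would not be available intraoperatively.

Early-biopsy metrics score each patient's first slide, and the elementwise
mean of the first two slides' probabilities for patients with ≥ 2 slides
(per-gene averaging; an any-mutant composite would be the alternative).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, per
patient: gene labels drawn independently per gene (defaults
ATRX 0.30, H3K27M 0.60, TP53 0.45 — chosen as plausible DMG-cohort
prevalences), a centre assignment, and a biopsy sequence that continues
until a Pass slide or a maximum of 6 biopsies, with P(No-Pass at order k)
defaulting to (0.45, 0.35, 0.25, 0.15, 0.10, 0) — this yields ≈ 1.7 slides
per patient and ≈ 40% No-Pass slides, matching the scale of a realistic
intraoperative cohort.

Each slide bag draws 30–80 patches of standard multivariate normal
background features. Mutant slides shift `round_half_up(fraction × N_x)`
"signal" patches by `effect_size` along a fixed, per-gene unit direction
(directions orthogonalised across genes and the PA label so signals do not
interfere); fractions default to 0.30 on Pass and 0.10 on No-Pass slides.
No-Pass slides of mutant patients additionally shift 20% of background
patches by a weaker "peritumoural" effect (0.30) along the same direction —
this shared weak signal is what makes Pass-to-No-Pass transfer detectable.
Every centre adds a constant N(0, 0.1²) offset vector. Reproducibility uses
one root seed with per-patient/per-purpose child streams
(`numpy.random.SeedSequence` spawn keys), so cohorts are identical across
runs regardless of generation order.

What this does **not** emulate: histological texture, scanner optics,
realistic foundation-model embedding distributions (which are not
characterised publicly), correlated gene labels, or label noise. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own assumptions — not clinical performance on real cryosections.

Synthetic slide images (for the preprocessing stage) are white backgrounds
with saturated elliptical blobs plus optional black marker strokes,
near-white holes and dust specks, and come with an exact ground-truth
tissue mask.

## Preprocessing

Fixed order: integer-factor area-average downscale (default 20×) → RGB to
HSV → saturation threshold (default 8/255) → median blur (kernel 7) →
morphological closing (4×4) → connected-component area filter (default 100
downscaled pixels). These defaults are exposed in `SegParams`; the
corresponding clinical pipeline's preset values are not published, so these
are declared package defaults, not inferred constants. Patch extraction
enumerates a stride grid (default 224, non-overlapping) of half-open
extents fully inside the image; a patch is kept iff its centre maps into a
retained region (centre-in-tissue, the simplest deterministic inclusion
rule). Coordinates are 0-based level-0 pixels, origin top-left, x = column.
The quality filter rejects a patch as `contaminated` when the fraction of
near-black pixels (all channels < 50) exceeds 0.30, else as `blank` when
mean RGB exceeds 230; contamination is checked first.

## Problem sizes and study conditions

The synthetic recovery study used by the tests and the acceptance script
runs at feature dimension 32 with ~200 patients, a 16/64 attention/MLP
width, 30 epochs and learning rate 1e-3 — small enough to train a dozen
models in well under a minute on one CPU while leaving the planted signal
(effect size 3.0) strongly recoverable. Package defaults remain the
reference protocol (768/64/1024, 80 epochs, lr 1e-4). The shuffled-label
control is evaluated on cross-validated predictions pooled over all five
folds: a single small test split has null-AUC sampling noise of ~0.09 SD,
and a noise-trained model's scores follow the dominant feature direction
with a random sign, so only the pooled control is expected to concentrate
near 0.5.

## Known limitations

- The feature backbone used on real slides (image translation + foundation
  model) is out of scope; bundled extractors are an identity map and a
  seeded random projection, sufficient to exercise the interfaces.
- The numpy training loop is single-threaded by design; it is not intended
  for 768-dimensional bags at clinical scale.
- DeLong coverage is mildly anticonservative at small n, as expected of the
  normal-quantile interval.
- The re-check simulation inherits the optimism of its design; it bounds,
  rather than estimates, the achievable biopsy reduction.
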