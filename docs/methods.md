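# Methods

## Scope and data model

The package implements the full analysis pipeline for three weakly
supervised classification tasks on melanocytic lesions — Spitz tumor vs
conventional melanoma (binary), the Spitz driver aberration grouped as
ALK / ROS1 / NTRK / other (four-class), and the diagnostic category
grouped as benign / intermediate / malignant (three-class) — plus a
Monte-Carlo simulation of how model recommendations would change the
pathology department's ancillary-testing workflow. A case is a lesion with
one or more whole-slide images; the classifier consumes the lesion's bag
of tile feature vectors produced by an external patch encoder, never the
pixels themselves. Raw clinical slide data for this problem are private,
so all experiments in the test suite run on cohorts from the synthetic
generator described below.

## Synthetic cohort generator

`CohortSpec` defaults encode the study cohort's composition: 772 lesions,
P(Spitz) = 393/772; aberration prevalences (59, 107, 111, 116)/393 for
(ALK, ROS1, NTRK, other), where the single ROS1 mutation is grouped with
the ROS1 fusions by gene; grouped category prevalences (209, 132, 52)/393
after merging the differential categories with the more severe side.
Clinical covariates are class-conditional: Spitz age ~ Normal(27, 12²)
truncated to [1, 73] years, melanoma age ~ Normal(48, 16²) truncated to
[3, 85]; sex P(male) = 0.300 (Spitz) / 0.417 (melanoma); six-level
anatomical site from the cohort percentages. A patient carries two lesions
with probability 0.1 (both share the pathway so patient-level splitting is
meaningful).

Feature bags are an isotropic Gaussian mixture. For each lesion a signal
fraction drawn uniformly from `signal_fraction_range` (default 0.1–0.6) of
tiles is centred on a class centroid; the rest are zero-mean background.
The centroid is `class_separation` times a combination of orthonormal
direction vectors (from a seeded QR decomposition): the pathway direction
plus, for Spitz lesions, half-weighted aberration and category directions,
so all three tasks carry signal in the same bags. Bag sizes are
log-uniform over `bag_size_range` (default 200–30,000, exceeding the
25,000-feature cap to exercise subset inference). The consultation domain
applies an affine shift (default scale 1.1, offset 0.2) to every vector,
a minimal stand-in for staining/preparation covariate shift. Signal tiles
sit at random positions, so tile order carries no label information by
construction.

What this generator does *not* emulate: the anisotropic, clustered
geometry of real encoder embeddings, spatial correlation between
neighbouring tiles, multi-slide heterogeneity within a lesion, and label
noise in the gold standard. Tests passing on these cohorts therefore
validate the pipeline's mechanics and statistics, not clinical
performance.

## Tessellation

Masks are binary tissue/pen maps at 1.25× magnification; tiles live at
20× (scale ratio 16), so a 224-px tile has a 14-px mask footprint. The
grid is anchored at the origin, 0-based, half-open, row-major; partial
edge tiles are discarded so all tiles have equal area. A tile is kept iff
its tissue coverage is ≥ 5% ("less than 5%" is excluded, so exactly 5%
is kept) and no pen pixel lies in its footprint (conservative reading of
the pen rule). Whether coverage should be computed on the 1.25× mask or a
higher-resolution map is not specified anywhere; footprint-on-mask is
used.

## Aggregator

Architecture: input projection D→192, learnable class token (Gaussian,
std 0.02), two pre-norm transformer blocks (4 heads, head dim 48, MLP
192→768→192 with exact-erf GELU), final LayerNorm, linear head. No
positional embeddings — the model is exactly permutation-invariant, which
the tests assert to 1e-5. Pre-norm blocks and the class-token
initialization are standard ViT conventions; the original block variant is
not documented, so these choices are fixed here for reproducibility.
Dropout during training: attention dropout p = 0.5 on the post-softmax
attention probabilities (inverted scaling), and tile dropout p = 0.5
implemented by excluding tiles from the sequence (at least one tile always
survives). Bags above 25,000 features are subsampled uniformly per
forward pass. The attention map is the head-averaged class-token→tile
attention of the final block, renormalized to sum to one; the extraction
rule is not documented for the original model, and last-block class-token
attention is the minimal faithful choice.

Forward and backward passes are hand-written NumPy (float32). The
backward pass is verified against central finite differences in float64
(relative error ~1e-4 tolerance in the test, observed ~1e-6). With both
dropout probabilities at zero, training-mode and evaluation-mode forward
agree exactly.

## Training protocol

Splitting is at the patient level: a stratified (by pathway) 75/25
development/test split, then five patient-level folds over the development
side, assigned greedily largest-patient-first into the lightest fold to
balance lesion counts. Fold stratification beyond pathway is not applied.

Per fold: cross-entropy, batch size one case, a fresh random case order
each epoch; gradients averaged over every 32 iterations before one AdamW
step (decoupled weight decay 0.01 — the coefficient is not documented, so
it is a configurable default — applied to weight matrices only); learning
rate 5e-5 halved after every 6,400 iterations; validation loss after every
320 iterations with the parameters at the minimum retained. The
diagnostic-category task uses balancing class weights
w_c = n/(k·n_c) in both the training loss and the validation loss used
for checkpointing (consistency choice). All randomness flows from one
seeded generator, so training is bit-reproducible.

Inference: bags over the cap are scored as the mean probability over 10
seeded random subsets of 25,000; the ensemble averages the five fold
models' probabilities. The binary decision threshold is fitted per fold on
its validation fold by exhaustive accuracy sweep over score-gap midpoints
(lowest maximizing interval wins; accuracy is the assumed objective); the
ensemble decides with the mean of the five fitted thresholds, since the
ensemble-level rule is not documented. Comparators: multinomial logistic
regression on standardized age, sex, one-hot six-level site, optionally
concatenated with the aggregator's pre-head class-token embedding (taken
per fold on its own validation cases during development; mean of the five
embeddings at test time, respecting the cross-validation boundary).

## Evaluation statistics

Accuracy is the exact fraction correct. AUROC is the Mann–Whitney
statistic with midrank (0.5) tie credit; multi-class AUROC is one-vs-rest
per class, undefined (NaN) for absent classes. Confidence intervals are
stratified-bootstrap percentile intervals (R = 10,000, strata = true class
label, preserving stratum sizes so class prevalence is fixed across
replicates). The binomial test against chance is one-sided ("greater") by
default since the scientific question is whether the model beats guessing;
sidedness is configurable. McNemar's exact test doubles the smaller
binomial tail of the discordant pairs, capped at 1, with b + c = 0 giving
p = 1; Bonferroni adjustment multiplies by the number of comparisons
(default 4) and caps at 1.

## Workflow simulator

Every case starts with one H&E examination at day 0 and ends resolved,
by a positive IHC stain or by molecular diagnostics (which always
resolves). Stains cost €100 and take 1 day; molecular costs €1,000 and
takes 10 days. A stain can only be positive for the matching aberration
("other" cases have no positive stain), and the matching stain fails with
probability 0.055 / 0.448 / 0.255 for ALK / ROS1 / NTRK; failure draws are
independent per stain per case visit. Examination counting: initial H&E
= 1, each sequential stain result = 1, a parallel stain round = 1, a
molecular result = 1 (this reproduces the canonical
H&E + IHC round + molecular = 3). Turnaround sums the processing days of
tests actually performed; the H&E day is day 0 (configurable convention).
The AI variants skip IHC when the predicted probability of "other"
strictly exceeds T = 0.5, and the probability-ordered sequential variant
sorts stains by descending predicted probability (prevalence order breaks
ties). The default prevalence order is NTRK > ROS1 > ALK, from the cohort
prevalences 28.2% > 27.3% > 15.0%. Summaries are means over 10,000
iterations of 100 cases sampled with replacement, with percentile 95% CIs
over per-iteration cost totals (the percentile convention matches the
bootstrap CIs used elsewhere). `expected_outcome` provides closed-form
per-case expectations for the non-AI variants and the perfect-oracle AI
variants by enumerating the outcome paths per class; the Monte-Carlo means
are tested against it within three standard errors. Predicted
probabilities can come from the trained ensemble, the perfect oracle, or a
synthetic noisy oracle, so the simulator is testable without a trained
model.

## Test-scale choices

The suite runs CPU-only, so the training experiments use reduced study
conditions chosen once: label recovery trains the 5-fold ensemble on a
500-case cohort (encoder dim 64, class separation 5 noise SDs, bags of
16–64 tiles) for 2,000 iterations and requires test AUROC ≥ 0.95; the
separation-monotonicity sweep uses 240-case cohorts (encoder dim 32, bags
8–32, 400 iterations) with medians over three seeds across separations
{0, 1, 2, 5}·noise_sd. Chance-level anchors use 100,000-lesion cohorts
(tolerance ±0.01); bootstrap coverage uses 200 simulations of n = 200 at
true accuracy 0.8 and must land in [0.90, 0.99]; the null distribution of
the binomial p-value is checked for uniformity by a KS test over 1,000
replicates of 5,000 trials.

## Known limitations

* The Gaussian-mixture feature model makes the tasks easier than real
  histology; absolute performance numbers on synthetic cohorts say nothing
  about clinical accuracy.
* No pretrained encoders are bundled; feature extraction is an interface,
  and bags must be provided (or generated) by the caller.
* Attention-overlay rendering, ROC curve plotting and calibration analysis
  are out of scope.
* The simulator models Spitz cases only, three stains, no false positives,
  and fixed costs/durations; these are the study's stated assumptions, not
  estimates from new data.
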