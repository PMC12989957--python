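# spitzmil

Attention-based multiple-instance learning for the classification of Spitz
tumors, with the surrounding analysis machinery: whole-slide tile-grid
construction, cross-validated training and ensembling, evaluation
statistics, and a Monte-Carlo simulation of diagnostic test-ordering
workflows.

## The problem

Spitz tumors are melanocytic lesions that histologically overlap with
conventional melanomas but are driven by different genetics (kinase fusions
in *ALK*, *ROS1* or *NTRK*, or other aberrations such as *HRAS* mutations,
rather than *BRAF*/*NRAS* mutations) and mostly behave benignly.
Distinguishing the two — and, for Spitz tumors, predicting the driver
aberration and the diagnostic category (benign / intermediate / malignant)
— normally requires immunohistochemistry (IHC) and molecular testing that
is slow and expensive. This package implements, as a fully testable
pipeline on synthetic data, the analysis by which an AI model can perform
these three classification tasks from whole-slide images and by which its
recommendations would change the pathology department's workflow.

## The model

A case is an unordered bag $X = \{x_1, \dots, x_T\}$ of tile feature
vectors ($x_i \in \mathbb{R}^D$, one per tissue tile of the slide at 20×
magnification). The aggregator is a small Vision Transformer used as a
permutation-invariant set classifier: each $x_i$ is projected to a
192-dimensional embedding, a learnable class token is prepended, two
pre-norm transformer blocks (4 heads, MLP ratio 4, no positional
embeddings) mix the set, and the classification head reads the final class
token. Training uses cross-entropy with AdamW
($\beta_1{=}0.9,\ \beta_2{=}0.999$) at batch size one for 32,000
iterations, gradients accumulated over every 32 iterations, learning rate
$5\times10^{-5}$ halved every 6,400 iterations, attention dropout and tile
dropout both at $p = 0.5$, a 25,000-feature cap with 10-subset averaging at
inference, 5-fold patient-level cross-validation, and probability averaging
over the five fold models. The per-tile attention map (head-averaged
class-token attention of the final block) localizes the evidence.

The network and its backward pass are written directly in NumPy, so the
whole pipeline runs on one CPU with no deep-learning framework.

Around the model: patient-level stratified splitting; accuracy and
(one-vs-rest) AUROC with stratified-bootstrap percentile CIs
($R = 10{,}000$); an exact binomial test against chance; exact McNemar
tests with Bonferroni correction for paired reader comparisons; logistic
regressions on clinical covariates (age, sex, site) alone or combined with
the model's case embedding; and a workflow simulator that prices IHC
stains (€100, 1 day) against molecular diagnostics (€1,000, 10 days) under
per-stain false-negative rates, with and without AI-based recommendations.

Real slides and encoder features for this problem are private, so the
package ships a synthetic-cohort module that generates labelled lesions
with realistic prevalences and clinical covariates, controllable
bag-of-features class signal, and an internal-vs-consultation domain shift.

## Worked example

`examples/simulate_workflow.py` draws a Spitz case pool at the study's
aberration prevalences (15% ALK / 27% ROS1 / 28% NTRK / 30% other) and
simulates 10,000 annual caseloads of 100 cases under each workflow
variant, with perfect AI recommendations for the AI arms:

```
variant                      cost €/100  days/case  exams/case
parallel                         82,750       6.27        2.53
sequential_prevalence            77,096       7.71        3.96
parallel_ai                      72,599       5.94        2.19
sequential_prevalence_ai         66,945       6.69        2.95
sequential_predprob_ai           63,149       6.31        2.57

closed-form parallel baseline: €800.61/case, 6.01 days, 2.50 examinations
```

Sequential staining is cheaper than parallel but slower and needs more
pathologist reviews; skipping IHC for cases predicted "other" and ordering
stains by predicted probability reduces cost and examinations further. The
closed-form line is the analytic expectation the Monte-Carlo run must
reproduce (the simulated €82,750 per 100 cases differs from 100 × €800.61
only through the finite pool's sampled class mix).

Other examples: `generate_cohort.py` (cohort composition),
`tessellate_mask.py` (tile grid and exclusion rules),
`train_and_evaluate.py` (5-fold ensemble on a separable synthetic cohort;
prints test AUROC 1.000 and accuracy 0.987 with a bootstrap CI),
`paired_comparison.py` (McNemar reader-vs-AI comparison).

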