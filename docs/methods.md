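# Methods

## Overview

`histomil` implements a cascade of weakly supervised models for molecular
subtyping of whole-slide histology after featurization.  The unit of data is
a *bag*: one slide represented as an ordered set of per-tile feature vectors
(a real deployment would obtain these from a frozen pretrained CNN; the
package defines the extractor as a pluggable contract and ships a synthetic
generator with planted ground truth).  The cascade is:

1. **Tiling** — a binary tissue mask is divided into complete, fixed-size
   square tiles (default 224 px ≈ 112 µm); a tile is kept when at least 50%
   of its pixels are foreground.
2. **Tile gate** — an MLP (input → 128 ReLU → sigmoid) scores each tile for
   lying in a neoplastic region; tiles with score strictly greater than 0.5
   pass the gate.  A second instance of the same architecture separates
   tumor cells from stroma among gated tiles.
3. **Slide classification** — a gated-attention MIL classifier maps the bag
   of gated tiles to the probability that the slide is basal-like rather
   than classical.  Each tile is embedded by an affine map to 128
   dimensions; attention logits are computed as
   `w·(tanh(V h) ⊙ σ(U h))` with 128 hidden units and softmax-normalized
   across the bag; the attention-weighted mean embedding passes through a
   128 → 64 → 1 ReLU head with a final sigmoid.  Loss: binary cross entropy
   against the patient-level binary RNA class inherited by each slide.
4. **Component regression** — a WELDON-style model scores every tile with
   four values (classical, basal-like, stroma-active, stroma-inactive) via
   an MLP (128 hidden units, ReLU); per component the slide output is the
   mean of the R = 100 largest and R smallest tile scores.  Loss: squared
   error against the patient-level continuous component scores, summed over
   components.
5. **Heterogeneity calling** — per patient, the 99th percentiles of tile
   basal and classical scores (pooled over all the patient's slides) feed a
   two-stage partition into main_classical / main_basal / hybrid /
   intermediary (below).

## Top/bottom-R pooling semantics

With `R' = min(R, n)` the pooled value is the mean of the 2R'-element
multiset of the R' top and R' bottom scores.  For `n < 2R'` the two sets
overlap and overlapping values count twice, so the statistic degenerates
continuously to the plain mean and a single-tile bag returns its own score.
The training gradient distributes `1/(2R')` per multiset membership, so
tiles in both sets receive twice the weight.

## Heterogeneity partition

For each patient let `delta = |p99_bas − p99_cla|` and
`max_level = max(p99_bas, p99_cla)`.  A two-component 1-D Gaussian mixture
(EM; quantile-based deterministic initialization; variance floor
`1e-8·var(x)`; tolerance 1e-6 on the log-likelihood; at most 500
iterations; components canonically ordered by decreasing mean) is fitted to
`delta`; patients assigned by maximum responsibility to the high-mean
component are *clear* and labeled main_basal when `p99_bas > p99_cla`, else
main_classical (ties break to classical).  Unclear patients are split on
`max_level`: the cutoff is the smallest point at which the high-mean
component of a second mixture (fitted to `max_level` over the full cohort)
takes posterior responsibility ≥ 0.5, evaluated on a 4097-point grid
spanning the observed range; `max_level ≥ cutoff` ⇒ hybrid, else
intermediary.  The cutoff can be overridden.  This specific construction of
the cutoff is our design choice — the underlying description ("an optimal
cut-off on the maximum level of differentiation") admits several readings —
chosen because it reuses the same mixture machinery as the first split and
involves no hand tuning.

Other boundary conventions, stated once and used everywhere: the neoplastic
gate keeps scores strictly greater than the threshold; the pure-classical
macro call requires *every* slide score strictly below 0.2; the
clear-RNA-subtype rule z-scores each component across the cohort and
requires the absolute scaled difference strictly above the cohort median
(so at most half a cohort is clear); basal-fraction bins are left-closed
right-open in percent, [0,5), [5,20), [20,100]; quantiles use linear
interpolation between order statistics (index `q·(n−1)`).

The "identified as basal-like" tile rule behind the basal-fraction table is
likewise not pinned down at tile level by its source; we min–max scale tile
basal scores against the cohort's pooled tumor tiles, require the scaled
score to exceed 0.5 and, when classical scores are supplied, the basal
score to exceed the classical one.  Both thresholds are parameters.

Whether the 99th percentile should be computed per slide and aggregated or
over tiles pooled across a patient's slides is ambiguous; we pool tiles
across slides.

## Optimization

No autodiff framework is used: the three architectures are small enough
that the gradients are derived analytically and verified against central
finite differences in the test suite.  Training uses Adam (lr 1e-3, β =
0.9/0.999), mini-batches of 256 tiles (tile models) or 8 bags (slide
models), early stopping on a 10% validation split with patience 5, and at
most 50 (tile) / 30 (slide) epochs.  During slide-model training at most
8000 tiles are uniformly resampled from each slide *per epoch* (re-sampling
acts as a mild regularizer); at inference all tiles are used.  All
randomness flows from explicit integer seeds through
`numpy.random.Generator`, so every fit is bit-reproducible.  Non-finite
losses abort training with a diagnostic rather than continuing silently.
A NaN-free forward pass is guaranteed by numerically stable sigmoid/softmax
implementations.  Class imbalance is not reweighted by default.

## Synthetic cohorts

The generator emulates a featurized slide cohort with known latent truth.
Per patient: an archetype (main_classical, main_basal, hybrid,
intermediary; default mix 192:84:45:130 — the proportions of a large
resected-cohort partition), a basal fraction `f` of tumor tiles drawn from
the archetype's distribution, and one or more slides of 120–240 tiles.
Tiles are neoplastic with probability 0.8; neoplastic tiles are stroma with
probability 0.4, else tumor.  Tumor tiles of the clear and hybrid
archetypes draw a pole (basal with probability `f`) and then a sharp Beta
phenotype near that pole (Beta(14, 1.5) / Beta(1.5, 14)); intermediary
tumors draw every tile from Beta(25, 25), concentrated at 0.5.  Stroma
tiles are active with a per-patient probability drawn from Beta(2, 2), so
stroma activation genuinely varies across patients and the bulk stroma
labels are recoverable rather than binomial noise.

Archetype basal-fraction defaults: clear archetypes draw `f` from
Uniform(0, 0.005) (mirrored for basal), hybrid from Uniform(0.35, 0.65),
intermediary from Uniform(0.45, 0.55).  The clear archetypes are given at
most 0.5% opposite-pole tiles deliberately: at desk-scale bag sizes the
99th percentile sits near the maximum, and a handful of contaminating tiles
would make a clearly differentiated tumor indistinguishable from a hybrid
one — on real slides with thousands of tiles the percentile is far more
forgiving.  This is the main respect in which passing recovery tests here
understates the difficulty of real data.

Features are class-conditional isotropic Gaussians in `feature_dim`
dimensions (default 64; 2048 supported).  Four orthonormal random
directions per run carry the neoplastic, cell-type, phenotype and
stroma-state signals; the tumor-tile mean interpolates linearly between the
classical and basal endpoints, whose separation is `class_sep · noise_sd`
(defaults 3 and 1).  At `class_sep = 0` features carry no information and
all classifiers sit at AUC 0.5.

Bulk labels: the basal component is the mean tumor-tile phenotype (plus
Gaussian label noise, sd 0.05), classical the mean of `1 − phenotype`,
stroma components the active/inactive stroma-tile fractions among
neoplastic tiles; the binary class compares the noiseless basal and
classical components with ties to classical.  Survival times are
exponential with log-hazard `survival_beta · basal_fraction`
(default β = 1.2, i.e. a hazard ratio ≈ 3.3 between fully basal and fully
classical tumors, consistent with the observed prognostic gap between those
groups), base scale 40 months, and independent exponential censoring
calibrated to a 30% censoring probability per subject.

What the generator does *not* model: pixel-level appearance, stain
variability, spatial autocorrelation of neighboring tiles, batch effects
between centers, and label noise structure beyond i.i.d. Gaussian/flip.
Recovery results on these cohorts demonstrate the correctness of the
machinery, not expected performance on real slides.

## A note on permutation nulls under planted separability

The shuffled-label control deserves a caveat.  When the planted signal is
strong, every bag's mean feature vector sits in one of a few clusters along
the phenotype axis, and bag-mean noise is ~N(0, σ²/n_tiles) — essentially
zero.  A model trained on shuffled labels therefore maps each *cluster* to
some baseline score (whatever best fits the shuffled labels in training),
and held-out scores collapse onto those baselines.  The held-out AUC
against the true labels is then decided by which cluster received the
higher baseline — a coin flip with extreme outcomes, not a draw
concentrated at 0.5.  Enforcing exact label/class independence in the
permutation does not change this.  Single-shuffle null AUCs should
therefore be read per fixed seed; the acceptance script reports the mean
over several shuffle repeats as the stable summary of the null.

## Statistics

Implemented from first principles (scipy supplies only distribution
functions): AUC as the Mann–Whitney statistic with half-credit ties and
DeLong structural-component variance for the normal CI (clipped to [0,1]);
Pearson correlation with the t-transform p-value; the Kaplan–Meier
product-limit estimator (median = earliest time with the estimate ≤ 0.5,
reported as not reached otherwise); the two-group log-rank test with
hypergeometric variance and tie correction, 1 df; Harrell's C over
admissible pairs (earlier time has an event and times differ) with tied
risks counting 1/2.  Cox regression is deliberately not implemented — the
package emits tidy survival tables consumable by standard survival
packages.

## Problem sizes

The recovery benchmarks use 200 single-slide patients (~120–240 tiles per
slide, 64 feature dimensions) with a 140/60 slide split, 100-patient
cohorts for subtype recovery, 200 simulations for log-rank type-I
calibration and 100 for power at hazard ratio 2 with 200 subjects per
group.  These sizes were chosen so the complete suite runs on a laptop in
well under a minute per model fit while leaving the planted-signal
conclusions unambiguous.

## Known limitations

* The per-tile phenotype poles and archetype distributions are synthetic
  stand-ins; their parameters are not constrained by any real cohort.
* Patient-level evaluation aggregates slide scores by the mean
  (configurable to max); the choice matters only for multi-slide cohorts.
* The gated-attention formulation follows the standard published
  construction (tanh ⊙ sigmoid branches, linear to one logit, softmax);
  the attention logit carries no bias term, which is irrelevant under the
  softmax shift invariance.
* `subsample_robustness` keeps at least one tile per slide, so extreme
  fractions on tiny bags are biased toward the full-bag score.
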