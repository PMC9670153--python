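# Methods

This note documents the models, procedures and design choices behind
`aufaces`: what the synthetic data emulate, how the classifier is built
and trained, how AU tuning is probed and summarized, and where the open
design decisions were resolved.

## Synthetic faces and the twin-culture model

**Renderer.**  Faces are drawn procedurally on a 2-D grid: a skin-toned
oval with a per-identity low-frequency shading field, brows as thick
segments, eyes as two-lobed ellipses with irises, a nose line with
nostrils, and a mouth built from four parabolic lip curves (outer/inner ×
upper/lower) meeting at the corners.  Each of the 20 emotion-linked AUs
displaces its control points *linearly* in its intensity t ∈ [0, 1] (the
mapping is tabulated in the renderer's docstring), so deformation
magnitude grows monotonically with intensity.  The canvas is rasterized
at 2× resolution and mean-pooled, and lip bands use exact box-filter
coverage, which keeps the L1 distance between a deformed and the neutral
render non-decreasing in t even after 8-bit quantization.  Two rendering
choices exist purely to preserve that monotonicity at desk resolution:
jaw AUs (#25/#26/#27) open the mouth downward with the upper lip fixed,
and lips are thick enough (> 2 px at the default 64 px) that a band's two
edges never alias within one pixel.  AU deformation coefficients are
calibrated so that the full-intensity pixel change is within a factor of
~6 across AUs; without this, the largest-deformation AU dominates every
normalized tuning profile.  Monotonicity is guaranteed at the default
64 px rendering size; coarser sizes (the minimum is 32 px) admit
quantization-scale wobble.

**Identities.**  A `FaceIdentity` holds bounded offsets (eye spacing and
size, brow height, mouth width and height, face aspect) plus a texture
seed; offsets are drawn uniformly within ±12 % (sizes) / ±0.012 of the
image side (positions), small enough that all features stay inside the
face oval.  The all-zero identity is the "average face" used as the probe
template.

**Culture maps.**  A culture assigns each expression label a sparse map
AU → (mean, sd); sampling draws each intensity from a truncated normal on
[0, 1] (sd = 0 returns the mean exactly; the default sd of 0.1 models
poser-to-poser variability).  The default twin fixture plants: happy =
AU12; surprised = AU1+2+5+26; fearful = AU1+2+4+5+20+25; disgusted =
AU9+10+17 (all shared between cultures); angry = AU4 + **AU22** in
culture A but AU4 + **AU23** in culture B; sad = AU1+15 in A, AU1+15+**22**
in B.  Anger's shared component (AU4) is kept at mean 0.4 so that the
divergent mouth AUs, not the shared brow signal, carry most of the angry
evidence — otherwise anger transfers across cultures and no
generalization asymmetry can appear.  Databases default to 60 identities
× 7 expressions, one image each.

What the generator does **not** emulate: photorealistic texture, 3-D
pose, lighting, occlusion, age/sex structure, correlated AU co-activation
beyond the planted patterns, and asymmetric expressions.  Passing tests
therefore show that the pipeline recovers planted AU structure under
identity and intensity noise — not that it would recover it from
photographs.

## Preprocessing

Grayscale conversion uses the Rec. 601 luma weights.  Face-region
extraction takes a bounding box from the synthesis manifest (for external
images a bbox column must be supplied; no detector is bundled, since
detection is not part of the analysis).  Histogram adjustment is the
affine map v′ = (v − mean)/sd · 32 + 128 with the **population** standard
deviation, computed over the crop before masking, then clipped to
[0, 255]; pre-clipping mean/sd hit the targets to machine precision.  The
oval mask blends linearly toward a flat background (default 128, so the
global mean barely moves) across a transition band of 5 % of the crop
height.  A pointwise linear blend cannot be exactly idempotent inside the
band (re-masking squares the blend weight); it is exactly idempotent
everywhere else, which is what the tests assert.

## Augmentation

Each standardized image expands into scales × offsets × reflections
variants in fixed lexicographic order; the full protocol is 5 × 5 × 2 =
50 (scales 0.90–1.10, offsets ±5 % of width, both reflections — the
magnitudes are free parameters of the protocol and these defaults are
modest, symmetric jitter).  Validation images are augmented identically
to training images.  Test evaluation uses only the single centered
un-augmented variant — the simplest reading of a protocol that does not
mention test-time augmentation.

## Classifier

A frozen convolutional backbone feeds a trainable three-layer head
(FC1/FC2/FC3, final width 7, softmax readout; inverted dropout 0.1 before
FC1 and FC2 in training mode only).  The default backbone is three frozen
stages of random 3 × 3 filters (He-scaled), ReLU, and 2 × 2 max-pooling
(64×64 → 8×8×32 = 2048 features); random frozen filters preserve enough
spatial structure to carry the planted AU signals, and a full pre-trained
conv stack can be plugged in from a weights file (never downloaded
silently).  FC weights are He-initialized — normal with sd √(2/fan-in),
biases 0; the cited initialization scheme fixes the scaling rule but not
the sd, so fan-in scaling is the documented choice.  Because the backbone
is frozen, features are extracted once per image and cached; training
touches only the head, implemented in NumPy with hand-written
backpropagation.

Backbone features are standardized (zero mean, unit sd per feature)
using statistics of the run's augmented *training* pool only; the
statistics are part of the trained model and are applied to validation,
test, swapped-database and probe inputs alike.  The per-feature sd is
floored at 1 % of the median sd so that features inactive on the training
distribution cannot produce unbounded responses on out-of-distribution
probe stimuli.

## Training protocol

Identities are split 40/8/12 (train/validation/test, scaled to the
database size); every augmented variant of a training identity is a
training sample, giving 14,000 training and 2,800 validation samples per
epoch at full scale.  Optimization is plain SGD (no momentum or weight
decay) on the softmax cross-entropy, batch 32 with a remainder batch,
under a piecewise-constant learning-rate schedule whose breakpoints take
effect immediately; training stops exactly at the iteration cap even
mid-epoch, because the cap (not the epoch count) governs the schedule.
At full scale the stated protocol of 12,000 iterations "over 29 epochs"
is arithmetically inconsistent with 438 iterations per epoch (438 × 29 =
12,702); the iteration cap is followed.  Validation accuracy is recorded
once per epoch; training accuracy is accumulated over augmented batches
as encountered.  Each experiment repeats the run with fresh
split/init/batch-order/dropout seeds spawned from a master seed through a
`SeedSequence` hierarchy (database A, database B, run group A, run group
B; four streams per run), making the whole pipeline bit-reproducible.

## Evaluation and statistics

Confusion matrices are computed per run on the centered variant of each
test image and averaged across runs; rows are true labels and sum to 1.
In the swapped condition, run *r* of one group is tested on the *other*
database restricted to the other group's run-*r* test identities, so both
conditions use equally sized, identity-held-out test sets.  Group
comparisons: Welch's two-sided t test (the unequal-variance choice is
deliberate; the design does not guarantee equal variances) on per-run
mean correct rates, and a two-way ANOVA (group × expression, type-II sums
of squares — immaterial in this balanced design, documented anyway) on
per-run per-expression rates, via statsmodels.

## AU probing and profile statistics

Probe stimuli pass through the same histogram adjustment and oval mask as
training data (the units were trained on that distribution) and are
presented once, centered, un-augmented.  Raw pre-softmax FC3 scores form
a 7 × 20 × 11 array; each unit's response to the null image is subtracted
(the intensity-0 cells then equal 0 exactly, and a spread above 1e-6
among a unit's null responses signals a corrupt probe set), runs are
averaged, and normalization — by the per-unit or per-group maximum
absolute response — is applied after averaging, for display and for the
PCA features.  Spearman statistics are computed on raw averaged profiles;
they are invariant to the positive rescaling of normalization (asserted
by test), so the choice is immaterial there.

Profile correlations flatten the 20 × 11 grid and drop the intensity-0
column: those cells are identically zero after baseline subtraction and
would inject 20 tied pairs; n = 200 pairs remain.  Spearman's rs uses
midranks for ties, with the large-sample two-sided t approximation for p
(adequate at n = 200; small-n exact work should use a permutation test).
Per-expression significance is Bonferroni-corrected at α = 0.05/7.  The
7 × 7 cross-group matrix exposes an orientation flag rather than a fixed
axis convention; when correlated with a swapped confusion matrix, the
row axis must be the group whose database supplied the test images, and
the helper verifies this before computing the 49-pair rank correlation.

For PCA, each profile reduces to 20 signed extrema (per AU the
largest-magnitude response across intensities, sign kept, magnitude ties
resolved toward the higher intensity — the stronger expression of the
AU).  Group-normalized profiles feed the 20 × 14 feature matrix so the
two groups enter on a common scale; PCA (scikit-learn) mean-centers but
does not variance-scale the 20 AU variables — the minimal standard
choice.  Scores are reproducible up to per-component sign flips, so
geometric tests compare pairwise distances.  At desk scale the feature
matrix is markedly low-rank (PC1 explains most variance): the small
backbone sees deformation magnitude more distinctly than deformation
identity, a known limitation of the desk-scale stand-in.

## Scale presets

| preset | image | identities (split) | variants | FC head | iterations (LR steps) | runs |
|--------|-------|--------------------|----------|---------|-----------------------|------|
| full   | 224   | 60 (40/8/12)       | 50       | 4096/4096/7 | 12,000 (4k/8k), LR 1e-4→1e-6 | 40 |
| desk   | 64    | 24 (16/4/4)        | 18       | 128/128/7   | 1,500 (500/1k), LR 1e-2→1e-4 | 5 |
| mini   | 64    | 18 (12/3/3)        | 12       | 64/64/7     | 1,200 (400/800), LR 1e-2→1e-4 | 3 |

The full preset exists for configuration validation (`--dry-run`); desk
and mini are the package's own working scales, chosen so that a full
twin-database experiment finishes in well under a minute (mini ≈ 20 s on
one CPU) while preserving every structural element: identity-disjoint
splits, a remainder mini-batch, stepped learning rate, multiple runs, and
all downstream statistics.  The mini preset is what the multi-seed
robustness suites and the acceptance script run.  Desk-scale learning
rates are larger than the full protocol's because the NumPy head trains
on standardized 2048-dim features rather than a pre-trained conv stack's
activations; 1e-2 with two ×10 decays reaches a stable plateau within the
iteration budget.

## Known limitations

- The synthetic renderer plants linear, independent AU effects; real
  faces have correlated, nonlinear AU interactions that single-AU probing
  cannot see (by design).
- Desk-scale accuracies and correlation magnitudes are not comparable to
  experiments on posed-photograph databases with a pre-trained backbone;
  only the directional findings (matched > swapped; shared expressions
  correlate, divergent ones do not; profile similarity predicts swapped
  choice rates) are expected to carry.
- The identical-cultures control still shows near-ceiling transfer rather
  than exact equality of matched and swapped rates, because the two
  databases hold different identities.
- Probe responses to AUs absent from a culture's training distribution
  are extrapolations; the feature-sd floor bounds but does not eliminate
  their out-of-distribution character.
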