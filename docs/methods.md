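# Methods

## The pipeline and its assumptions

The package implements the computational stages of a knee-radiograph
synthesis study: prepare real knee-joint crops, train a Wasserstein GAN with
gradient penalty (WGAN-GP) per merged severity class (KL 0–1 vs KL 2–4),
select the best epoch by Fréchet distance, audit for training-set
memorization, score an expert realism survey, and measure augmentation and
anonymization-by-replacement effects in a binary severity classifier. The
pipeline assumes 8-bit single-channel knee crops of uniform size with a
manifest carrying KL grade, laterality and exclusion flags; it does not
perform joint detection or bounding (assumed done upstream).

## Preprocessing

**Histogram equalization.** `h(v) = round(255·(cdf(v) − cdf_min)/(m·n − cdf_min))`
over 256 integer bins, with half-up rounding for bit reproducibility. For a
constant image the denominator is zero; the image is returned unchanged with
a warning rather than raising, since a degenerate radiograph should surface
downstream, not crash a batch run.

**Focus filtering.** The image is convolved with the discrete Laplacian
`[[0,−1,0],[−1,4,−1],[0,−1,0]]`; the focus statistic is the **sum** of
squared deviations of the absolute response from its mean — not a mean —
because the conventional rejection threshold (350) is tied to that
unnormalized statistic. The convolution-mode ambiguity (a padded response
has the input's m×n size but contaminated borders) is resolved by defaulting
to the valid (m−2)×(n−2) response, with a `mode="same"` reflect-padded
option for comparison. The threshold is chosen from an inclusive grid
(default 0–525 in steps of 175, giving candidates {0, 175, 350, 525}) whose
partitions are reported for qualitative inspection; `variance < t` marks an
image blurry. Blurry images are kept in a separate manifest because the
augmentation experiment reuses them as its scarce real pool.

**Orientation and polarity.** Right-oriented images are mirrored to the
left; laterality is trusted from the manifest. Negative (inverted-channel)
images are detected by a border-vs-centre heuristic — radiographs have dark
air borders and bright bony centres, so a 5% border frame whose mean exceeds
the central region's mean flags a negative, which is restored as
`255 − pixels`. No published rule exists for either detection; the
heuristics are this package's choices and are validated against phantom
ground truth.

**Pipeline order** is flip → invert → equalize → rescale (bilinear,
anti-aliased, default 210×210) → focus split, with artifact/excluded rows
dropped before the split. Focus scores are therefore computed on equalized,
resized images.

## Networks and training

**Architectures.** The generator maps a 50-dimensional standard-normal
latent vector through a bias-free dense layer to 100,352 features, batch
normalization, ELU(α = 0.2), a reshape to 14×14×512, three nearest-neighbour
upsample + 3×3 bias-free conv(128) + ELU stages, a final upsample +
conv(1), per-channel batch normalization, tanh, and a 7-pixel crop:
224 → 210. The critic zero-pads 210×210×1 by 2 and applies five 5×5
stride-2 'same' convolutions (64/128/256/312/422) with ELU, dropout 0.3
after the second and third, a flatten to 20,678 features, dropout 0.2, and
a linear unit. Parameter totals — generator 6,304,900 (6,104,194 trainable;
the difference is the batch-norm moving statistics), critic 6,335,861 — are
asserted in tests and recomputed by `scripts/acceptance.py` from the
instantiated arrays. Batch normalization uses ε = 10⁻³ and momentum 0.99.

**Objective.** Critic loss `E[D(fake)] − E[D(real)] + λ·E[(‖∇ₓD(x̃)‖₂−1)²]`
with λ = 10 and x̃ = ε·real + (1−ε)·fake, ε ~ U(0,1) per sample; generator
loss `−E[D(fake)]`. The original saturating GAN objective is provided as a
documented function only and is never trained. Real images are scaled to
[−1, 1] by `x/127.5 − 1` to match the tanh output; 8-bit export inverts
this with `(x+1)·127.5` rounding.

**Optimizer and schedule.** Adam with l = 2·10⁻⁴, β₁ = 0.5, β₂ = 0.9 and
per-update inverse-time decay `l/(1 + d·t)`, d = 10⁻⁴, with an exponential
option `l·e^(−d·t)`. The critic takes 4 updates per generator update by
default ("three extra steps"), configurable to 3 — the parameter totals and
every tested guarantee are unaffected by the ratio. An optional
critic-only warm-up phase (`critic_warmup_steps`) trains the critic before
adversarial updates begin, the standard recipe for making the critic's
Wasserstein estimate a faithful distance from the start of training;
the smoke tests use 80 warm-up steps.

**Differentiation.** The network core is a NumPy reverse-mode
implementation: every layer backward-propagates to both its parameters and
its input, so a full backward pass yields ∇ₓD(x) exactly — the quantity the
gradient penalty's *value* needs, and the route the generator's gradient
takes through the critic. The penalty's contribution to the critic's
*weight* gradient formally needs second derivatives; it is computed as
`∇_θ‖g‖ = ∇_θ[(D(x̃+εu) − D(x̃−εu))/(2ε)]` with `u = g/‖g‖` held fixed — two
ordinary backward passes around a central difference (step 10⁻², data scale
[−1, 1]) instead of a second-order graph. All layer gradients are verified
against finite differences in the test suite; dropout masks are frozen per
penalty evaluation so the three passes see the same network.

**Scaled spec.** Desk-scale runs use the same topology at 64×64 (latent 16,
base 4×4×64, three 32-filter stages, no crop; critic filters
16/32/32/32/48). Smoke training uses 64 phantoms, batch 16, 80 warm-up + 120
adversarial critic steps — sizes chosen so a run finishes in about two
minutes on one CPU while still exhibiting a declining Wasserstein estimate.

## Model selection and the memorization audit

The Fréchet distance between Gaussian fits,
`‖μ_g−μ_r‖² + tr Σ_g + tr Σ_r − 2·tr((Σ_gΣ_r)^{1/2})`, uses 1/(n−1)
covariances and `scipy.linalg.sqrtm`, clipping small negative round-off at
10⁻⁶. A literal variant with `tr(√(Σ_g+Σ_r))` in place of the matrix-product
root is available behind `formula="printed"` for forensic comparison; it is
not a distance (nonzero on identical inputs) and is never the default. The
extractor is pluggable; the default is a seeded random-projection embedding,
which preserves every metric property the tests rely on (an InceptionV3-type
embedding can be slotted in where pretrained weights are available). Epoch
selection samples a fixed-seed batch per checkpoint, embeds, scores, and
returns the argmin epoch (ties to the earliest) plus the full curve.

The memorization audit pairs each generated image with its nearest real
embedding by Euclidean distance and exports the closest `top_k` (default 20)
as a side-by-side montage for expert review. No automatic verdict is made —
judging replication is a human step — but pairs closer than the 1st
percentile of real–real distances are flagged as a heuristic aid.

## Survey scoring

Balanced accuracy `½(TP/(TP+FN) + TN/(TN+FP))` handles missing responses;
missing calls are excluded per expert, never imputed. The positive class for
precision/F1 defaults to "fake" (the detection task) and is switchable.
Group summaries are unweighted means over experts with sample (n−1) SDs;
experts outside the qualifying specialties (orthopedic surgery, radiology)
are excluded. KL rating agreement collapses grades with {0,1} → KL01,
{2,3,4} → KL234 and averages per-expert match fractions per
(real/fake × class) cell, excluding experts with no ratings in a cell.
Undefined metrics (zero denominators) are reported as NaN, not 0.

## The augmentation / anonymization experiment

Six dataset plans: baseline 100 real training images per class with 66-image
per-class validation and test sets (all real, pairwise disjoint, drawn once
from a pool of at least 232 images per class); four augmentations that
recursively extend the training set with 50/100/150/200 extra generated
images per class (each a superset of the previous); and a replacement plan
whose training set is generated-only. The transfer classifier is a VGG16
convolutional base sized to produce a 6×6×512 map, with blocks 1–4 frozen —
the printed non-trainable total 7,635,264 equals blocks 1–4 exactly, which
settles the ambiguous "last three blocks trainable" phrasing in favour of
block 5 + dense head + output — a 256-unit ELU dense head and a sigmoid
unit. Backbone weights are randomly initialised here; parameter totals are
weight-independent, and accuracy-bearing runs would slot in pretrained
weights. Transfer-training hyperparameters are not fixed by the published
record; the default is Adam at 10⁻⁴, documented as a gap. Grayscale inputs
are replicated to three channels for the backbone. Desk-scale experiment
runs use a small CNN stand-in with the same training contract
(best-validation-loss checkpointing, Table-4-shaped output columns).

## What the phantoms establish — and what they do not

The phantom generator produces deterministic knee-like images: two
horizontal bone bands separated by a class-dependent joint gap (severe class
0.4× gap, doubled osteophyte count), a fibula marker fixing laterality,
seeded osteophyte bumps, then blur → inversion → noise → scratch in that
order (noise after blur mimics detector noise on a smoothed signal), with
mirroring applied last so left/right twins are bit-exact mirrors. Phantoms
carry the statistical structure the pipeline's decisions depend on (class
separation, orientation, polarity, focus continuum, artifacts) and ground
every preprocessing check in known truth. They are *not* anatomically
faithful: passing tests demonstrate the correctness of the algorithms and
the trainability of the networks at desk scale, not clinical realism of
generated images, which requires real radiographs and expert review.

## Numerical choices and limitations

* float32 throughout the network stack; metric computations in float64.
* Equalization rounding is half-up; resizing is bilinear with anti-aliasing.
* FID tie-breaks to the earliest epoch; negative round-off clipped at 10⁻⁶.
* Dropout uses inverted scaling; masks derive from per-step child seeds, so
  runs are bit-reproducible for a fixed config seed on one platform.
* Full-size (210×210, 1000-epoch) training is supported by the same code
  path but is a multi-day CPU job; tests and examples use the scaled spec.
* The Wasserstein-estimate decline asserted in smoke tests is a stochastic
  property; it holds for the pinned seeds and the documented warm-up recipe.
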