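# Methods

## Pipeline overview

An input image passes through four stages: (1) Gabor filter-bank
denoising, (2) mixed depthwise-convolution feature extraction, (3)
stacked-GRU classification, and (4, optional) chaotic sparrow search over
the classifier's hyperparameters, minimizing the validation error rate.
Every stage is deterministic given the master seed: stage seeds are drawn
from `default_rng(master_seed)` in a fixed order (split, extractor,
training, tuning).

## Gabor preprocessing

The kernel is a Gaussian-windowed complex sinusoid on the integer offset
grid; ψ = 0 selects the even (real) filter used throughout. Parameters,
with defaults:

- `delta` — carrier wavelength, pixels; default 4 (matches the fixture
  gratings' scale at side 64).
- `theta` — orientation, radians, normalized into [0, π); the bank uses
  {0, π/4, π/2, 3π/4}.
- `gamma` — spatial aspect ratio; default 0.5 (mildly elongated fields,
  the common texture-analysis setting).
- `bw` — spatial-frequency bandwidth, octaves; default 1. When given,
  σ is derived from the closed form and a user-supplied σ must agree to
  1e-12 relative, preventing silently inconsistent kernels.
- kernel support: half-extent `ceil(3σ)` (≥ 99.7 % envelope mass);
  convolution is true convolution with reflect padding, output the same
  size as the input, so small tiles avoid edge artifacts.

The stage is exposed as `denoise` because that is its pipeline role; the
kernel itself is band-pass and orientation-selective, not a Gaussian
blur, and the module documentation says so explicitly. Color inputs
collapse to the channel mean — the simplest reproducible luminance rule.

## Feature extractor

A stack of [MDConv → pointwise 1×1 → ReLU] blocks with global average
pooling; defaults: 3 blocks, widths (16, 32, 64), MDConv kernel sizes
(3, 5) split over two contiguous equal channel groups (fewer groups when
the channel count is too small, e.g. the 1-channel input block). Stride 1
and zero same-padding everywhere; depthwise filtering uses the
cross-correlation convention standard in convolutional networks. This is
deliberately the smallest structure that exercises every mechanism the
cost formulas describe; it is not a replica of any published
architecture, and no pretrained weights are involved. Weights are
He-initialized from the extractor seed and fixed; an optional warm start
copies weights from another identically configured extractor. The
feature length equals the last width (64), chosen so the default
sequence chunking (4 steps × 16) divides it evenly.

## Stacked GRU classifier

Feature vectors are standardized (train-split mean/std) and chunked in
index order into `seq_len = 4` steps. The stack default is 2 layers,
hidden size 16; layer i ≥ 2 consumes layer i−1's hidden state at the
same step; h₀ = 0. Training defaults: plain SGD, learning rate 0.01,
dropout 0.5 on inter-layer hidden states only (inverted dropout,
disabled at inference), batch size 5, 50 epochs, cross-entropy loss.
Gradients are derived analytically (backpropagation through time across
the stack) and verified against central finite differences in the test
suite; no autodiff framework is used. Two runs with the same seed
produce bit-identical parameters.

Numerical choices: sigmoid computed via the sign-split stable form;
softmax shifted by the row max; log-loss clipped at 1e-300. Epoch 0
returns the untouched initialization.

## Chaotic sparrow search

Minimization over a box, population N, T iterations. Per iteration:

- **Discoverers** — the best `pd_frac = 0.2` fraction (a conventional
  setting in the sparrow-search literature). One warning draw R2 per
  iteration; below the safety value ST (default 0.8) each discoverer
  shrinks multiplicatively by `exp(−i/(αT))` with rank i and
  α ~ U(0,1] (0 excluded to avoid overflow); otherwise it takes one
  shared-across-dimensions N(0,1) step.
- **Joiners** — the remainder, by fitness rank i. Rank > N/2 jumps to
  `Q·exp((x_worst − x)/i²)`; otherwise the sparrow moves to the current
  best plus the dimension-averaged signed absolute offset
  `(1/D)·Σ_d rand(−1,1)·|x_d − x_best,d|` (a fresh draw per dimension,
  averaged to a scalar — mirroring the mean-form follower move of the
  original sparrow search).
- **Vigilantes** — `sd_frac = 0.1` of the population, sampled without
  replacement. Not-at-best sparrows move relative to the worst position
  with an N(0,1) step length; the at-best branch uses the guarded step
  `K·|x − x_worst|/((f_i − f_w) + e)` with K ~ U(−1,1) and `e = 1e-8`
  (float-stability constant; it alone prevents a zero denominator when
  f_i = f_w).
- **Chaotic refinement** — logistic map at μ = 4 from seed ρ₁ = 0.3
  (the map's rational fixed points 0.25/0.5/0.75 are rejected), mapped
  into the box as `P = a + ρ(b − a)` so the candidate is always feasible,
  blended with the best by `SC = (T − t + 1)/T`, and accepted only on
  strict improvement (greedy elitism). The best-so-far history is
  therefore non-increasing by construction.

Bounds are enforced by projection (clipping) after every phase — the
simplest deterministic repair. One fitness evaluation per sparrow per
iteration plus one for the chaotic candidate: N·(T+1) + T evaluations,
reported in the result. Note the multiplicative discoverer shrink biases
the search toward the origin; on origin-centered benchmarks (sphere)
this flatters convergence, which is why the random-search comparison at
an equal budget is the meaningful check.

Hyperparameter tuning decodes positions per declared dimension
(log-scale for learning rate, rounding for integers) and evaluates the
validation error rate of a shortened training run (default 10–15 epochs
during the search). One population member is warm-started at the default
configuration, so the tuned result can never be worse than the default
under the same objective — a deliberate design choice that makes tuning
a strict refinement rather than a gamble.

## Metrics

One-vs-rest binarization per class, seven measures in percent, macro row
as the unweighted mean over classes computed on unrounded values.
Rounding is half-up to 2 decimals at report time only. A zero denominator
reports 0.00 and flags the class as degenerate instead of raising,
because small synthetic runs legitimately produce empty predicted
classes. The forced choice of one-vs-rest (rather than micro) averaging
is what makes per-class accuracy and specificity exceed the overall
accuracy, as in standard multiclass report tables.

## Synthetic fixtures

Each of the 8 classes is a parametric texture family: an oriented
sinusoidal grating (orientation k·π/8, frequency 0.08 + 0.015k
cycles/pixel for class index k) plus a Gaussian-blob field (3 + 2k blobs
per 64² pixels), with per-image phase, ±5° orientation and ±5 % frequency
jitter, corrupted by additive Gaussian noise (σ = 0.08 in [0,1] units by
default — enough to blur class boundaries without destroying them).
Default counts are 106/237/115/130 benign and 788/137/169/138 malignant
(1820 images, side 64); `scaled(f)` takes `max(8, floor(count·f))` per
class to preserve the imbalance at desk scale.

What the generator emulates: class count imbalance, an 8-way texture
signal with tunable difficulty, and deterministic regeneration. What it
does not emulate: stain variability, tissue morphology, scanner
artifacts, intra-class heterogeneity of real histology. Passing tests
therefore demonstrate the pipeline's mechanics and learnability on
controlled texture statistics — not clinical performance.

## Problem sizes used in validation

The end-to-end checks run on 0.1-scale fixtures (177 images, side 64),
extractor widths (16, 32, 64), hidden size 16, 50 training epochs, and a
small tuning budget (population 4, 2–3 iterations, 10–15 epoch objective
trainings) — sizes chosen so a complete validation pass is a
minutes-scale, single-CPU job while still exercising every stage at
realistic dimensionality. The optimizer checks use the 5-D sphere with
N = 20, T = 100 over 20 seeds.

## Known limitations

- The joiner far-half move `Q·exp((x_worst − x)/i²)` collapses positions
  toward the origin scaled by a single Gaussian draw; combined with the
  discoverer shrink this makes the optimizer origin-biased. Shifted or
  ill-conditioned objectives (Rosenbrock) converge much more slowly.
- The vigilante branch condition keys on `f_i ≠ f_g` (moving not-at-best
  sparrows toward the worst position's neighborhood); variants of the
  sparrow search in the literature use `f_i > f_g`. The printed-form
  branch is implemented; at desk scale the difference did not change any
  qualitative behavior covered by the tests.
- SGD training of the GRU stack is sensitive to feature scale; the
  pipeline's train-split standardization is load-bearing.
- The feature extractor is untrained (random projections); class
  information reaches the classifier through the Gabor-band statistics
  of the texture families. For harder data the extractor's warm-start
  hook is the intended extension point.
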