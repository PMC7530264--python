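# Methods

This note documents the model behind each pipeline stage, the defaults
and the reasoning behind the genuinely open design choices.

## Signal model and the heat-map representation

A recording is a channels × samples matrix in µV at 256 samples/s. The
pipeline assumes that class information lives in the *frequency content*
of a small set of high-variance channels: slow oscillations render as
smooth vertical bands in the composed image, fast oscillations as rough
texture, and texture statistics of the image then act as a proxy for the
spectral contrast between classes.

Conditioning runs in four steps:

1. **Channel selection.** Default: the fixed 11-electrode list FP1, FP2,
   F7, F8, T7, T8, CZ, C3, C4, CP5, CP6 (frontal, temporal and central
   sites with the most intense activity). Common printings of this list
   carry a duplicated T7 token; the package uses the 11 unique labels.
   Alternatively `channel_mode="top-k"` selects the k channels with the
   highest mean sample variance across recordings (ties broken
   lexicographically so the ranking is total and reproducible).
2. **Outlier removal at ±73.3 µV.** Excursions beyond the threshold are
   movement artifacts. Default mechanism is *clipping* (saturation),
   which preserves the fixed time axis the image needs and is
   idempotent; `outlier_mode="drop"` instead replaces offending samples
   by linear interpolation of their nearest in-range neighbors
   (endpoints take the nearest valid value). Clipping is the default
   because dropping changes local texture more aggressively and the
   removal mechanism is otherwise unconstrained.
3. **Min-max normalization to [0, 1]**, by default over all selected
   channels *jointly*, so between-channel amplitude ratios survive;
   per-channel scope is available behind `normalization_scope="channel"`.
   A constant (zero-range) recording maps to all zeros.
4. **Quantization** to `quant_levels` (default 256) integer levels with
   round-half-up, `q = floor(x·(levels−1) + 0.5)` — symmetric and
   platform-stable. Quantization is monotone by construction.

**Composition.** Time runs down the rows (default `time_length` 1024 —
one default synthetic recording fills the image exactly; shorter inputs
error unless `pad_mode="edge"`), channels across the columns in blocks
of `block_width` = 32 identical columns. 11 channels × 32 px = 352
columns; replication (rather than interpolation) fills the block, which
keeps composition exactly invertible (averaging a block recovers the
quantized series) and produces the flat/rough band texture the
descriptors consume. Images are stored as 8-bit grayscale PNG.

## Texture descriptors

**GLCM.** Pair counts at distance 1 in four directions (0°, 45°, 90°,
135°), accumulated, symmetrized (each pair counted both ways) and
normalized to a joint distribution p(i, j) over 256 gray levels. The
direction set, distance, level count and symmetry are conventional
defaults and configurable. All 14 Haralick statistics are computed with
base-2 logarithms and the 0·log 0 ≡ 0 convention; the sum-variance
statistic is taken about the sum average; degenerate denominators
(zero-variance marginals in the correlation, zero marginal entropy in
the first information measure, an undefined second eigenvalue in the
maximal correlation coefficient) return 0. The implementation is
verified against an independent per-definition brute-force oracle and,
for the co-occurrence counting, against scikit-image's `graycomatrix`.

**LBP.** Code = Σₚ f(gₚ − g_c)·2ᵖ with f(x) = 1 for x ≥ 0 — an exact tie
with the center sets the bit. Neighbors sit at angles 2πp/P on the
radius-R circle and are bilinearly interpolated; because the
displacement is constant across centers, interpolation reduces to a
fixed-weight combination of four shifted array slices (fast and exact
for axis-aligned neighbors). The ≥ comparison carries a 1e-9 slack that
absorbs floating-point noise when the interpolated neighbor ties the
center. The 48-feature default is P=8 at R ∈ {1, 2, 3} with 16
equal-width bins over [0, 256) per radius, each histogram normalized to
sum 1. Codes depend only on gray-level differences, so features are
invariant to additive gray shifts absent saturation.

**Hu moments.** Central moments about the intensity centroid give
translation invariance; normalization η_pq = μ_pq / μ₀₀^α with
α = (p+q)/2 + 1 gives scale invariance (verified to 1e-3 under 2×
nearest-neighbor upscaling, and against scikit-image's `moments_hu`).
The truncated exponent α = (p+q)/2, which appears in some printings but
is *not* scale invariant, is available via `exponent="printed"` for
comparison. The seven standard invariant combinations φ₁..φ₇ follow.

Descriptors are computed on the whole composed image, not per channel
block: the image as a whole is the representation under study.

## Deep features

Backbones are *injected* as callables (prepared array → final activation
volume), so the package carries no deep-learning framework dependency;
the registry pins each of the 12 supported architectures to its
canonical input size and post-pooling feature dimensionality (e.g.
MobileNet 224×224 → 1024, NASNetLarge 331×331 → 4032). Preparation is
bilinear resize, grayscale→RGB by replication, and the architecture
family's usual pixel scaling ([−1, 1], ImageNet standardization, or mean
subtraction). Global average pooling of the final stack reproduces the
registered dimensionalities. `load_keras_backbone` builds the real
architectures (randomly initialized unless ImageNet weights are
explicitly requested) when TensorFlow is installed.

## Synthetic data

The generator produces what the pipeline assumes and nothing more: 64
named 10-10 channels at 256 Hz, 1024 samples; the 11 default-selected
channels carry the class signal — a sum of `n_components` = 3
equal-amplitude sinusoids with random phases and random frequencies
drawn *on the DFT grid* inside the class band (control 1–7 Hz, alcoholic
20–50 Hz), so the noiseless spectral support is exactly the band; white
Gaussian noise everywhere (σ = 5 µV); Bernoulli(0.001) per-sample
artifacts replaced by ±90 µV spikes, deterministically beyond the
±73.3 µV rule. Total band amplitude defaults to 20 µV;
`amplitude_ratio` scales the alcoholic class (1 = equal power). Defaults
were fixed once as plausible resting-EEG magnitudes: ~20 µV oscillatory
amplitude against ~5 µV sensor noise keeps the active channels clearly
but not trivially above the noise floor.

What it does *not* emulate: 1/f background spectra, event-related
potentials, stimulus structure, eye-blink morphology, inter-channel
correlation. Passing tests therefore show that the pipeline recovers
*planted spectral structure*; they say nothing about effect sizes in
real recordings.

Per-recording seeds are spawned from the dataset seed via
`SeedSequence`, so any subset regenerates identically.

## Evaluation protocol

Ten stratified random 80/20 train/test splits (the "ten subsets with a
proportion of 80% for training and 20% for tests" reading of repeated
shuffle splits), and inside each training portion a 20-iteration random
search scored by stratified 10-fold cross-validated accuracy; ties keep
the first candidate. All randomness derives from one integer seed.

Hyperparameter domains: kNN k ∈ odd {3..15}; MLP one hidden layer with
2–1000 neurons sampled log-uniformly; SVM kernel ∈ {linear, poly, rbf},
C = 2ᵉ for e ∈ {−5..15}, γ = 2ᵉ for e ∈ {−15..3} (rbf), degree ∈ odd
{3..9} (poly); RF criterion ∈ {gini, entropy}, min_samples_split ∈
{2..6} (a minimum of 1 cannot define a split, so the domain starts at
2), min_samples_leaf ∈ {1..6}, 3,000 trees (fixed, not searched);
Gaussian NB has no hyperparameters. The MLP trains with adam and a
bounded iteration count — Levenberg–Marquardt training is not available
in mainstream Python ML stacks and the optimizer is not what the
protocol exercises.

Metrics come from one-vs-rest confusion counts per class: accuracy
(tp+tn)/n, precision tp/(tp+fp), recall tp/(tp+fn), F1 their harmonic
mean, each **macro-averaged** over the two classes with equal weight and
reported in percent. Any 0/0 is defined as 0. Macro averaging plus this
zero convention gives constant predictors exact closed forms (e.g. a
constant majority predictor on an 18-sample set with 11 majority members
scores macro precision 30.56, recall 50.00, F1 37.93), which the tests
pin exactly.

## Problem sizes in the test suite

The end-to-end recovery test uses 30 recordings per class, the default
1024 × 352 images, LBP features, and a random-forest evaluation with 10
outer splits but a 5-iteration search over 5 inner folds with 100-tree
forests — a deliberate scale-down of the default grid (3,000 trees,
20 × 10 search) chosen so the whole suite runs in minutes on one CPU;
the quantity under test is class recovery (≥ 90% macro accuracy, with a
label-permuted control at chance), which is insensitive to forest size
at this sample size. All other tests run on small matrices or 8×8–9×9
patches.

## Known limitations

- The UCI-style text dialect is fixed as '#'-comments plus 4-field
  records; archive quirks beyond that (gzip bundles, error trials) are
  out of scope. How 1,024 time points relate to ~1 s trials at 256
  samples/s is resolved by concatenating trials along time.
- Variance ranking averages per-recording sample variances; computing
  variance over concatenated records instead would weight long
  recordings differently.
- Pretrained ImageNet weights are download-gated and never exercised by
  tests; deep-feature tests cover geometry and determinism, not
  representational quality.
- The permutation-null check uses a 3σ band with a binomial floor on σ
  (a constant predictor can report zero between-split spread while the
  per-split mean still carries ~±4.6% sampling noise on 12-sample test
  sets).
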