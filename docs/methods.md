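# Methods

This note records the models, conventions and design choices behind
`erisnet`, in the order data flows through the package.

## Images, units and the 8-bit boundary

A `CTImage` is a 2-D grid of Hounsfield units (HU) with physical pixel
spacing; all noise statistics (ROI analysis, the phantom noise model) are
defined in HU. The network consumes 8-bit arrays: `hu_to_uint8` maps a
configurable linear window (default soft tissue, center 40 HU, width
400 HU) onto [0, 255], clipping outside and rounding half-up, so a pixel
at the window center maps to 128. The window travels with the `Image8`,
making the mapping invertible up to clipping and half-gray-level
quantisation (≈0.78 HU at the default window). Whether a fixed window or
per-volume scaling should feed the network is genuinely open for this
architecture class; the fixed window is the documented default because it
makes the 8-bit domain identical across patients, and per-use-case windows
can be passed anywhere an `Image8` is produced. Metrics are computed on
the 8-bit arrays with L = 255; HU-domain evaluation is possible by passing
raw arrays and `MetricParams(L=window_width)`.

DICOM I/O is single-frame CT via pydicom, honoring RescaleSlope/Intercept
(stored values are int16; the write→read round trip is exact to half a
stored unit). Slices are ordered by instance number, not file name.

## The synthetic phantom

The generator emulates the *statistics* a paired high/low-dose CT study
rests on, not CT physics:

- **Geometry** — five elliptical organ-like regions (vitreous body, brain,
  liver, spleen, paravertebral muscle) on a water-equivalent body disk
  over a −1000 HU air background. Ellipses give the edges that SSIM and
  EPI need to be meaningful. Mean attenuations (18.75, 45.50, 59.00,
  54.61, 52.12 HU) are typical parenchymal values for these tissues.
  Organ shapes are specified in millimetres; the default pixel spacing
  scales so any resolution covers the same 512 mm field of view.
- **Noise** — i.i.d. additive Gaussian in HU with σ(f) = σ_full/√f for
  dose fraction f, the quantum-noise heuristic that makes the dose knob
  physically meaningful. σ_full defaults to 13.5 HU so that low-dose noise
  sits near 20 HU at the typical ~55% dose reduction — the 17–26 HU
  regime seen in soft-tissue reconstructions. Chosen once from the dose
  model; it is a modelling default, not a fitted value.
- **Dose reductions** — one per patient, uniform on [41%, 83%] (mean
  ≈ 55%); an explicit per-patient list can be supplied instead. Per-patient
  anatomical variation is a small jitter of organ centers and sizes.

What the phantom does *not* emulate: correlated/streak noise, beam
hardening, metal artifacts, scanner reconstruction kernels, or anatomical
realism. Tests passing on the phantom demonstrate that the pipeline is
correct and that the network can learn this noise model — not that the
trained weights transfer to clinical scans.

## Network

Encoder (two conv→ReLU→2×2-max-pool stages), middle conv with dropout,
decoder (two 2×2 transposed-conv ×2 upsampling stages), DnCNN refinement
head, final 1-filter conv. Conventions chosen where the architecture
description leaves room:

- 3×3 kernels with shape-preserving padding; two pooling stages, so
  inputs must be divisible by 4 (checked, with the divisor in the error).
- Skip connections are channel concatenations of each encoder stage's
  pre-pool activations with the matching decoder stage, followed by the
  decoder convolution (the U-Net lineage).
- The DnCNN head's unit is one block = conv → batch-norm → ReLU →
  dropout; `convs_per_block=2` builds the two-convolutions-per-block
  reading instead. Both are constructible; one conv per block is the
  default because the block count is the tuned hyperparameter.
- Direct image prediction by default; `use_global_residual=True` adds the
  input back so the stack predicts the noise (the classical DnCNN
  formulation).
- He-uniform initialisation for convolutions, batch-norm scale 1/shift 0,
  all seeded; two builds from the same seed are bit-identical.
- Inference runs with dropout off and batch-norm running statistics, and
  is deterministic; large images are convolved in row chunks to bound
  im2col memory (≤256 MiB per buffer).

The default configuration is the tuned one: encoder (64, 96), middle 112,
decoder 96, 4 DnCNN blocks, dropout 0.5. (The tuned summary elsewhere
lists encoder width 96; the architecture diagram's (64, 96) is used as
the default and a single int `enc_channels=c` expands to (c, c), so both
are reachable.) Parameter count is a pure function of the configuration:
k²·c_in·c_out + c_out per convolution, 4·c_in·c_out + c_out per 2×2
transposed convolution, 2c per batch-norm.

Everything is NumPy: im2col + BLAS matmuls forward, analytic backward
passes verified against numeric differentiation, Adam with standard
moments. The reference kernels (`convolve2d`, `relu`, `maxpool2d`,
`batchnorm`, `dropout_mask`) are the element-wise definitions each layer
is tested against.

## Training

MSE loss on [0, 1]-scaled 8-bit pairs; Adam; batch size 6 and learning
rate 3·10⁻³ by default (the tuned values — note the tuning search space
for the learning rate was 10⁻⁵–10⁻⁴, so the printed final value lies
outside it; the printed value is kept as the default and both are
reachable). Fixed epoch count with best-on-validation checkpointing, since
no stopping rule is part of the tuned configuration. Patient-level
splitting guarantees no subject appears in two subsets. Augmentation
applies one rotation (uniform in ±10°, bilinear, −1000 HU fill) and
independent horizontal/vertical flips (p = 0.5) identically to both
members of a pair; derived pairs carry an `augmented` provenance flag and
the trainer refuses augmented validation data.

The hyperparameter search is a seeded random sampler over the stated
fine-tuning space (dropout 0.4–0.5; encoder {64, 96, 112}; middle
{96, 112, 128}; decoder {64, 96, 112}; DnCNN blocks {3, 4, 5}; learning
rate log-uniform 10⁻⁵–10⁻⁴; batch {4, 6, 8}), minimising validation MSE
with a replayable trial log. A Bayesian/TPE sampler would explore more
efficiently at large budgets; at desk budgets (tens of trials) random
search over this small space is adequate and has no extra dependencies.

**Desk scale.** The test suite trains on 23 synthetic patients × 10
slices at 64×64 (15/4/4 split, factor-4 augmentation, 10 epochs,
batch 6) with a reduced channel plan (`DESK_CONFIG`: encoder (8, 12),
middle 16, decoder 12, 2 DnCNN blocks, no dropout, global residual on).
The residual formulation matters at this width: a small direct predictor
spends its whole capacity reproducing the sharp air/tissue boundary,
while the residual net preserves it for free and learns only the noise
correction. This run improves held-out PSNR by ~3.3 dB and SSIM by ~0.17
over the low-dose input in a few CPU-minutes.

## Metrics

MSE, PSNR (infinite for identical images; serialised as `inf`), and
population-variance NV are computed exactly as defined. Two metrics have
two defensible readings, so both are implemented and reports always label
the mode:

- **SSIM** — `global` evaluates the single luminance/contrast/structure
  statistic over whole images (population moments); `windowed` (default
  for reports) is mean local SSIM over 11×11 Gaussian windows (σ = 1.5),
  delegated to scikit-image with population covariance. Reported SSIM
  values in the denoising literature are windowed; the global statistic
  is kept as the formula-level definition and oracle target.
- **EPI** — `paper` is the quotient of summed squared gradient
  differences over summed squared reference gradients (forward
  differences, edge replication): 0 means perfect preservation.
  `correlation` (default for reports) is the normalised cross-correlation
  of gradient magnitudes: 1 means perfect preservation, matching the
  ~0.97 scale on which edge preservation indices are reported.

VIF is the pixel-domain multi-scale realisation: per scale (4 scales,
×2 Gaussian smoothing and decimation between scales), local means,
variances and covariance under a Gaussian window estimate a gain-plus-
additive-noise channel, and VIF is the ratio of summed
log(1 + g²σ²_ref/(σ²_v + σ²_n)) to summed log(1 + σ²_ref/σ²_n) with HVS
noise σ²_n = 2.0. It equals 1 for an identical pair and decreases with
distortion. The wavelet-domain GSM formulation is out of scope. VIF and
EPI are reference-anchored (not symmetric); a constant reference makes
them undefined and is reported as an error, and `evaluate_dataset`
records such failures per pair instead of dropping rows.

## ROI analysis

Circular ROIs of physical radius (default 8 mm) use a center-in-circle
pixel inclusion rule (a pixel belongs iff its center is within the
radius), which has an exact lattice-count oracle (197 pixels at 8 mm,
1 mm spacing). Anisotropic spacing turns the circle into an ellipse in
pixel space. ROI statistics use the sample SD (n−1); the NV metric is the
population variance as defined — at ROI sizes of ~200 pixels the
difference is negligible for the percent-reduction arithmetic. ROI
placement is user-supplied; the phantom exports canonical per-organ
centers so the five-organ analysis is scriptable.

## Reader-study statistics

Score reconstruction enumerates all C(n+4, 4) multisets of n scores from
{1..5} (210 for n = 6; bounded at n ≤ 12) and accepts those whose mean,
sample SD, median and IQR (linear interpolation of order statistics)
round half-up to the printed summary at each value's printed precision;
integral printed values (median 5, IQR 0) are matched as exact, since on
the quarter/sixth grids these statistics occupy, an integer can only
arise exactly, and integer-precision matching would make most summaries
ambiguous. Exactly one colliding pair of 6-score multisets exists at
2-decimal precision; it is reported as an ambiguity error listing both
candidates. Reconstruction reproduces unrounded downstream arithmetic:
printed t statistics match the reconstructed-score computation, not a
recomputation from the rounded SD.

Per question: two-sided one-sample t-test against the neutral midpoint 3
(scipy), Cohen's d = (mean − 3)/SD (so t = d·√n identically), standard
error SD/√n, and the 95% CI half-width t₀.₉₇₅,ₙ₋₁·SE. The Holm
adjustment runs jointly across questions in two variants:

- `standard` — the step-down Holm–Bonferroni procedure (statsmodels):
  sorted p's multiplied by (k − i + 1), running-maximum monotonicity,
  capped at 1.
- `tie-averaged` — each p multiplied by (k − rank + 1) with *average*
  ranks over ties and no monotonicity pass. This is not a proper
  step-down procedure, but it is what several spreadsheet/point-and-click
  implementations emit for tied p-values, and it is the convention behind
  the published table this package reproduces (for tied questions the two
  variants differ: 0.0072 vs 0.0078 at k = 9). Both variants agree on the
  smallest p-value.

The default is `standard`; reproduction of the published table uses
`tie-averaged` explicitly.

## Numerical and testing notes

- All randomness flows through `numpy.random.default_rng` seeds; datasets,
  builds, training runs and searches are reproducible bit-for-bit (up to
  BLAS accumulation order for training).
- float32 parameters and activations for training; gradient correctness is
  tested in float64 against central differences.
- Problem sizes in the test suite (64×64 training slices, 512×512 for the
  single full-configuration inference check, ≥10⁵ pixels for Monte-Carlo
  noise recovery) were chosen so the whole suite runs in minutes on one
  CPU core while keeping every statistical tolerance honest.
- Known limitations: no compressed or multi-frame DICOM; the phantom's
  noise is white and stationary; the NumPy backend trains desk-scale
  configurations only — the full (64, 96)/112/96 plan is exercised in
  inference but training it to convergence is a GPU-framework job.
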