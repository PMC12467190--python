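# erisnet

Noise reduction for low-dose CT with a convolutional encoder–decoder +
DnCNN refinement network, together with the complete evaluation stack a
denoising study needs: six paired image-quality metrics, circular-ROI
Hounsfield-unit noise analysis, and reader-study (Likert) statistics.
A built-in synthetic phantom generator produces paired high/low-dose
slices so every stage is runnable and testable without access to clinical
data.

The package is aimed at medical-imaging researchers and engineers who want
a transparent, dependency-light reference implementation of this class of
denoiser and of the statistics used to evaluate one. The network and its
training loop are implemented directly in NumPy (im2col convolutions,
analytic backward passes, Adam), so every layer is inspectable and unit
tested against brute-force oracles.

## The model

ErisNet maps a 1-channel 8-bit CT slice to a denoised slice of the same
size:

- **Encoder** — two stages of 3×3 convolution → ReLU → 2×2 max-pool,
  with 64 then 96 filters (defaults), halving resolution twice.
- **Middle** — 3×3 convolution (112 filters) → ReLU → dropout (p = 0.5).
- **Decoder** — two 2×2 transposed-convolution upsampling stages
  (96 filters) with skip connections: each encoder stage's pre-pool
  features are concatenated into the matching decoder stage before a 3×3
  convolution.
- **DnCNN head** — 4 blocks of convolution → batch-norm → ReLU → dropout
  at full resolution, then a final 1-filter convolution producing the
  output. An optional global residual (`use_global_residual`) switches to
  the classical DnCNN noise-prediction formulation.

Training minimises `MSE(f(x_LQ), x_HQ)` on [0, 1]-scaled 8-bit images with
Adam (batch 6, learning rate 3·10⁻³ by default), with patient-level
train/val/test splitting (15/4/4), factor-4 paired augmentation (±10°
rotations, horizontal/vertical flips with p = 0.5, the *same* transform
applied to both members of a pair), and best-on-validation checkpointing.

Evaluation metrics (on 8-bit arrays, peak value L = 255):

- MSE, PSNR = 10·log₁₀(L²/MSE), noise variance NV = (1/mn)·Σ(I − μ)²;
- SSIM, both as a single global statistic and as sliding Gaussian-window
  SSIM (11×11, σ = 1.5);
- pixel-domain multi-scale VIF (mutual-information ratio through the
  distortion channel vs the reference channel);
- EPI in two modes: the literal gradient-difference quotient (0 = perfect
  edge preservation) and gradient-magnitude correlation (1 = perfect).

ROI analysis places circles of fixed physical radius (8 mm) on HU slices
and reports mean/SD and the percent SD reduction
`100·(SD_LQ − SD_out)/SD_LQ`. The reader-study module reconstructs
6-rater Likert score sets exactly from printed summary rows (exhaustive
search over the 210 multisets), then computes one-sample t-tests against
the neutral midpoint 3, Cohen's d, 95% CIs, and joint Holm adjustment.

## Worked example

Desk-scale end-to-end run: generate 23 synthetic patients × 10 paired
64×64 slices, split by patient, train the reduced channel plan for 10
epochs, and score the held-out patients:

```python
import numpy as np
from erisnet import (make_paired_dataset, split_by_patient, build_erisnet,
                     DESK_CONFIG, TrainConfig, train, denoise, hu_to_uint8,
                     psnr, ssim)

pairs = make_paired_dataset(n_patients=23, slices_per_patient=10,
                            size_px=(64, 64), seed=42)
tr, va, te = split_by_patient(pairs, (15, 4, 4), seed=42)
net = build_erisnet(DESK_CONFIG, seed=42)
net, history = train(net, tr, va, TrainConfig(epochs=10, seed=42))
```

Scoring the test patients (see `tests/test_acceptance.py` for the full
loop) prints:

```
held-out PSNR: LQ 27.49 dB -> denoised 30.82 dB
held-out SSIM: LQ 0.548    -> denoised 0.715
```

The denoiser adds ~3.3 dB of PSNR and 0.17 of SSIM over the low-dose
input on patients it never saw.

The reader-study pipeline needs only the printed summary rows:

```python
from erisnet import TABLE_SUMMARIES, analyze_table
from erisnet.reader_stats import results_to_frame

results = analyze_table(summaries=list(TABLE_SUMMARIES),
                        holm_variant="tie-averaged")
print(results_to_frame(results)[["Q1", "Q3", "Q9"]].round(4).to_string())
```

```
                Q1      Q3       Q9
mean        4.5000  4.6667   4.8333
median      4.5000  5.0000   5.0000
sd          0.5477  0.5164   0.4082
iqr         1.0000  0.7500   0.0000
se          0.2236  0.2108   0.1667
critical_t  2.5706  2.5706   2.5706
ci_width    0.5748  0.5419   0.4284
ci_min      3.9252  4.1247   4.4049
ci_max      5.0748  5.2086   5.2618
t           6.7082  7.9057  11.0000
p_raw       0.0011  0.0005   0.0001
p_holm      0.0072  0.0042   0.0010
cohens_d    2.7386  3.2275   4.4907
```

Each column is one questionnaire item: the reconstructed integer scores
behind it, the t statistic against the neutral score 3, raw and
Holm-adjusted p-values, and the effect size.

A command-line interface wraps the same functions: `erisnet simulate`,
`erisnet train`, `erisnet denoise`, `erisnet evaluate`, `erisnet roi`,
`erisnet reader-stats` (see `--help` on each).

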