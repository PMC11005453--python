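# Methods

## Model and assumptions

The network is a 2-D encoder–decoder for binary (cell/background)
segmentation of single-channel microscopy frames. It assumes images whose
spatial size is divisible by 2^(depth−1) and whose intensities are scaled to
[0, 1]. The backbone keeps the nnUNet conventions that matter for
small-batch microscopy training — instance normalisation instead of batch
normalisation, leaky rectifiers (slope 0.01), strided-convolution
downsampling, transposed-convolution upsampling — but none of nnUNet's
automatic self-configuration machinery (fingerprinting, plan files,
ensembling), which is out of scope.

Two attention mechanisms sit at the decoder junctions:

* **gⁿConv** applies n recursive elementwise gates over feature groups whose
  widths double per order (C_k = C/2^(n−k−1)). Before the operator runs, the
  map's channels are laid out on a √C₀ × √C₀ spatial grid with H₀·W₀
  channels, so the gating mixes *channels* of the original map — this is
  what makes it act as channel attention. The statement of this reshape in
  the source material is dimensionally inconsistent as written; the package
  uses grid side = √C₀, the unique choice that conserves element count and
  reproduces the printed 22 ↔ 484 pairing.
* The **nested transformer** mixes the up-sampled feature, the down-sampled
  feature, the gⁿConv-refined feature, and a bottom-up multi-scale bundle
  through residual cross-attention, a rectifier FFN, and a convex α-fusion
  (α on the up-sampled side).

Decisions taken where the design was genuinely open:

* **Recursion order.** The gating follows the cited gⁿConv reference design:
  the width-raising projection is applied to the carrier before each gate
  and the first step is identity-width. Each gate output is scaled by
  1/√C_k for numerical stability (the source is silent on stabilisation).
* **Normalisation and projections.** Q/K/V receive learned linear
  projections to the common token width (an identity-projection mode exists
  for oracle tests); pre-norm layer normalisation is the default with a
  no-norm switch; no positional encodings (none are described for this
  architecture); dropout (0.1) sits after each attention and inside the FFN.
  The attention formula is single-head as printed; `heads` is configurable.
* **Junction wiring.** Token widths are indexed bottom-up over the depth−1
  junctions, default 484 for all but the topmost and 256 there, mirroring
  the published per-layer channel list. The lowest junction has no incoming
  bundle, so its carrier x_c is initialised from the down-sampled feature's
  tokens. Every junction aggregates a 4-part bundle; the topmost bundle has
  no consumer and is therefore aggregated without learned weights (a
  learned projection there would be a dead branch).
* **Aggregation H.** Concatenation + linear projection is the default
  encoding strategy. The "interpolation" alternative combines parts with
  equal fixed weights after resampling to a common grid; because the parts
  have unequal feature widths, each part first passes through its own linear
  map to the target width (the functional identity-projection form requires
  equal widths).
* **Ablations.** `use_transformer=False, use_gnconv=True` injects the
  channel attention residually (x_u + gⁿ(x_u)) before the skip
  concatenation; with both flags off the forward pass is exactly a plain
  U-Net, verified against an independently coded oracle to 1e-5.
* **Token-grid cap.** Spatial-token attention is quadratic in H·W. The
  `max_token_grid` option bilinearly resamples the features entering a
  junction to at most that grid and resamples the refined feature back,
  bounding the attention cost; with the cap unset the computation is exact
  at every junction. The desk-scale configuration caps at 16.
* **Head and binarisation.** Final activation is a per-pixel two-way
  softmax; masks are obtained by channel argmax (ties fall to background).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gn_order` n | 3 | interaction order; gates per gⁿConv pass |
| `token_widths` | (484, …, 256) | per-junction token feature width d |
| `ffn_hidden` | 2048 | FFN inner width |
| `dropout` | 0.1 | after attention and inside the FFN |
| `alpha` | 0.3 | fusion weight on the up-sampled feature (3:7 ratio) |
| `depth` / `width_schedule` | 5 / (32…512) | resolution levels and conv widths (2-D nnUNet convention; the source prints no encoder widths) |
| `pad_policy` | `pad` | zero-pad channels to the next perfect square; `strict` rejects |
| learning rate / momentum | 0.01 / 0.99 (Nesterov) | SGD with polynomial decay, power 0.9 |
| loss | soft-Dice + cross-entropy, equally weighted | nnUNet convention; the source does not state its loss |
| `folds` / `val_fraction` | 5 / 0.2 | cross-validation protocol (80:20 per fold) |

The published gⁿConv operating point is exposed two ways — the 22 × 22 grid
(484 reshaped channels) and the per-level channel rule 9·2^(2i) — because
the two printed descriptions cannot both apply to the same tensors; the
package takes no position on which the original build used where.

## Synthetic scenes

The generator emulates confocal frames of the corneal stroma: sparse
elongated bright ellipses (keratocyte bodies, intensity falling off toward
the edge) on a dark background with a linear illumination gradient and
Gaussian noise, in three regimes — `clear`; `occluded`, where dark
random-walk vessel streaks are drawn over the *image only* while the mask
keeps the true cell extent; and `blurred`, Gaussian defocus plus contrast
compression. The default regime mix (24:10:6 per 40 images) mirrors the
test-split condition proportions of the clinical material the package
emulates. Scenes are pure functions of their configuration, masks are
analytic ellipse unions (so mask/image registration is exact), and boundary
sharpness decreases strictly from clear to blurred at fixed seed.

What the generator does **not** model: real keratocyte morphology variation
(dendritic processes, activation states), disease-specific cytology
(keratoconus vs herpes-simplex erosion), speckle statistics of laser
scanning, depth-dependent attenuation, or annotation noise. Passing the
training probes therefore shows that the architecture, gradients, and
pipeline work end-to-end and can fit cell-like structure under occlusion and
blur — not that clinical-grade accuracy is reached on real corneal images.

## Numerical choices

* All arithmetic in float64 on a purpose-built NumPy reverse-mode autodiff
  engine; convolution via im2col, transposed convolution as the exact 2×2
  pixel-block expansion, bilinear resampling with the align-corners endpoint
  convention (identity when sizes match).
* Initialisation: truncated normal (std 0.02, resampled beyond 2σ) for
  projections, He-scaled normal for conv stages; all draws from one seeded
  generator, so two builds from the same configuration are bit-identical.
* Softmax is max-shifted; normalisation layers use ε = 1e-5; the soft-Dice
  loss uses ε = 1e-6; Dice of two empty masks is defined as 1, and
  zero-denominator precision/recall follow the "1 if the queried set is also
  empty, else 0" convention. Pixel-wise AUC is the Mann–Whitney statistic
  (ties ½) and is reported missing for single-class images and excluded
  from aggregates. Aggregation is the unweighted per-image mean (macro) by
  default, with a pixel-pooled micro option.
* Training aborts with the offending step index on a non-finite loss.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on tensors of a few thousand elements. The two
end-to-end probes use the reduced configuration (depth 3, widths 8/16/32,
token width 64, FFN 128, token grid capped at 16) on 64 × 64 scenes with
five cells each: a 300-step overfit probe on 16 scenes and a 300-step
generalization run on 32 training / 8 validation scenes — sizes chosen so
the full pipeline, including both attention mechanisms, trains to
high Dice in minutes on a single CPU core. The consistency checks on the
published benchmark tables allow one printed ulp (0.01) of slack, since the
overall Dice is printed with inconsistent rounding in the source tables.

## Known limitations

* No 3-D variant, deep supervision, ensembling, mixed precision, or
  multi-device training.
* The engine favours clarity over speed; full-scale 384 × 384 / depth-5
  training is possible but slow compared to GPU frameworks.
* Uncapped spatial-token attention at high-resolution junctions is
  quadratic in pixel count; use `max_token_grid` for large inputs.
* Boundary-distance metrics (Hausdorff, ASSD) are deliberately absent.
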