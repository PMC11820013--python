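# Methods

## Model

One slide is a bag X ∈ ℝ^{N×C_in} of patch feature vectors with a
binary label; no instance labels are ever shown to the model. The
forward pass is

    encoder → cascaded attention block → decoder → attention pooling → FC → sigmoid

**Encoder / decoder.** Single affine maps with ReLU: C_in → C_model and
C_model → C_model. The published description names both components
without giving their internals; the single-layer reading is the
smallest architecture in which both exist and both matter. C_model
defaults to 256 for 512-dim CNN features; the desk-scale studies in
this repository use C_model = 128 on 64-dim synthetic features (chosen
once for CPU runtime; results were not tuned against it).

**Spatial attention.** A = XW_A + b_A, B = XW_B + b_B,
D = XW_D + b_D, all C×C with bias. The attention matrix is
column-stochastic: S[i, j] = softmax over i of A_i·B_j, i.e. column j
holds the influences of every instance i on instance j. The refined
matrix is E = α·SᵀD + X.

**Channel attention.** Logits are the channel Gram matrix EᵀE; the
softmax again runs over the influencing index for each target channel,
and G = β·E·Cmat + E. In the source description the softmax
denominator index for this module nominally runs to N although the
matrix is C×C; it is read as a typo for C (the Gram matrix is over
channels), and that reading is what the loop oracles verify.

**Residual gates.** α and β are learnable scalars initialized to
exactly 0. Consequences, all tested: the block is the identity map at
initialization; the whole model then coincides bit-for-bit with a plain
attention-pooling MIL baseline sharing the remaining weights (exposed
as fusion mode `"none"`); and training opens the context pathways only
as far as they reduce loss.

**Fusion modes.** `spatial_then_channel` (default; best AUC/recall in
the published ablation), `channel_then_spatial`, `spatial_only`,
`channel_only`, and `parallel_concat`, which concatenates the two
module outputs along channels and projects back to C with a learned
2C×C map. The concatenation reading of "parallel" fusion is a design
choice; the projection keeps every downstream shape mode-independent.

**Pooling and head.** Instance scores from a two-layer tanh scorer
(hidden width 128 by default) are softmax-normalized over instances —
the canonical attention-MIL pooling — and the weighted average feeds a
linear classifier with sigmoid output. The classifier weights
initialize at zero so an untrained model outputs probability exactly
0.5; gradients reach the rest of the network from the second step on.

**Numerics.** Everything is float64. Both attention softmaxes subtract
the per-column maximum before exponentiation, which is exact by shift
invariance and necessary because raw 512-dim dot products overflow
exp. The dot products are deliberately NOT scaled by 1/√C — the model
equations have no such factor, and the zero-initialized gates already
keep early training stable. The loss is binary cross-entropy on the bag
logit, computed through a stabilized softplus.

**Autodiff.** The model runs on a small in-package reverse-mode tape
(`camil.autodiff`) over NumPy rather than a deep-learning framework.
The engine supports exactly the dozen operations the model needs;
gradient correctness is enforced by finite-difference tests across all
fusion modes.

## Training and evaluation

Adam (β₁ = 0.9, β₂ = 0.999) with initial learning rate 1e-4 and L2
weight decay 1e-5 added to the gradient; one bag per step; cosine
annealing lr(t) = lr₀·½(1 + cos(πt/(T−1))) over the T = 50 epoch
budget; early stopping on validation AUC with patience 10. The
published recipe names the early-stopping mechanism but not its
monitor; AUC is used because it is the headline metric. Among epochs
with equal validation AUC the parameters with the lowest validation
cross-entropy are kept: AUC is rank-based and saturates long before the
logit scale calibrates, and without the tie-break ACC@0.5 lags AUC
badly.

Evaluation reports accuracy at threshold 0.5, ROC AUC (Mann–Whitney,
ties at ½, via scikit-learn), specificity, recall and F1 (defined as 0
when precision + recall = 0). Cross-validation is stratified at slide
level (both motivating datasets are imbalanced) with a seed-determined
assignment; each training fold reserves a stratified 20% for early
stopping. A fixed train/test entry point (`fit_and_score`) is also
provided, matching the alternative fixed-split protocol.

## Interpretation

Grad-CAM is adapted to bag models: the instance-level raw score is
ReLU(∂logit/∂h_j · h_j) at the post-attention embedding h_j (the layer
is configurable: encoder, attention or decoder output). Scores are
min–max normalized per slide; a constant raw vector maps to all zeros
rather than an arbitrary constant. Heatmaps paint each patch's
half-open footprint [x, x+s)×[y, y+s) with a diverging colormap (warm
= high); overlapping footprints resolve by pixelwise maximum to
preserve hotspots, and unpatched background stays transparent.

## Preprocessing

Tiling is non-overlapping 256×256 by default at 20× and/or 10×, with
10× derived from a 20× raster by exact 2×2 block averaging; border
tiles that do not fit are dropped, and coordinates are always reported
as 0-based level-0 pixel offsets of the patch corner. Tissue detection
(unspecified in the source): HSV saturation thresholded by per-slide
Otsu, with a fixed fallback threshold of 0.15 when the saturation
histogram is degenerate (an all-background or all-tissue field has no
two modes for Otsu to split). The 35% area filter is strict — patches
with less than the threshold are discarded, so fraction = 0.35 is
kept. Slide input is limited to plain PNG/TIFF rasters that declare
their magnification; pyramidal SVS reading would require a slide
backend not bundled here.

## Synthetic data

`make_bags` emulates the statistical core of the WSI task: instances
are standard Gaussians in `feature_dim` channels; a positive bag gets
⌈witness_rate·N⌉ witness instances shifted by `effect_size` on the
first `signal_channels` channels. Defaults — witness rate 0.1 (tumor
area is typically under 10% of a positive slide), effect size 2, 8
signal channels, 20–60 instances per bag, balanced labels — define the
package's study conditions. The desk-scale experiments use 200 bags
and 64 input channels. What this generator does **not** model: spatial
correlation between neighboring patches, stain/batch variation,
instance-count correlation with the label, and label noise. Passing
the synthetic studies therefore demonstrates that the optimization,
attention mechanics and weak-supervision bookkeeping work — not
clinical performance, which requires the real benchmarks (out of scope
here).

`make_slide` renders white canvases with saturated pink disks plus the
exact mask, giving the preprocessing tests a ground-truth answer.

## Reproducibility

All randomness flows from explicit seeds; the CLI fans one global seed
into per-stage substreams (seed·1000003 + crc32(stage), mod 2³¹), and
each stage writes a manifest with the config hash so reruns are
byte-identical. `scripts/acceptance.py --seed S --out f.json` re-runs
the signal-recovery study (3 derived seeds), the null control, and the
oracle/identity/gradient/preprocessing checks, writing each measured
value with its problem size.

## Known limitations

- CPU-only and O(N²) in bag size for spatial attention: bags beyond a
  few thousand instances become slow; the real-WSI regime would need
  the optional CNN encoder plus batched linear algebra.
- The pretrained CNN encoder requires the `cnn` extra (torch); without
  it the deterministic histogram encoder stands in, which is
  informative for color-based synthetic fixtures only.
- Binary labels only; one magnification per feature store.
- The null-control band ([0.35, 0.65] AUC) is a distributional sanity
  check, not a formal test of calibration.
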