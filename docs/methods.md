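# Methods

## Model

`edgeflow` estimates the density of normal-image features and scores
deviations from it. Let x be an input image (square, side divisible by 64,
grayscale replicated to three channels, normalized (p − 0.5)/0.5 by default).
A frozen convolutional backbone produces a pyramid F₁…F₄ at sides H/8, H/16,
H/32, H/64. Each pyramid level is treated as a field of per-position feature
vectors z^k; scale-specific conditional normalizing flows map these fields to
latents u^k whose likelihood under a standard normal, corrected by the exact
flow log-determinant, is the model's density estimate. Anomalies — image
regions unlike anything in the normal training set — receive low density.

### Backbone

Two extractors share the H/8…H/64 spatial scheme:

- `table2-resnet18`: ResNet18-style (7×7 stem + max pool + four stages of two
  basic blocks, widths 64/128/256/512). The stem applies one extra spatial
  halving (stride-4 stem conv) so stage 1 sits at H/8; a config flag restores
  the standard stride-2 stem (stage 1 at H/4). The architecture choice of a
  stride-4 stem rather than an extra pool is ours: only the resulting shapes
  are fixed by the target configuration, not the operator that produces them.
- `tiny-test-backbone`: four strided 3×3 convolutions with configurable small
  widths (default (4, 8, 16, 32) in the desk-scale profile). Its convolutions
  are **linear** — no rectification. With random frozen weights, ReLU would
  discard half of every intensity shift and measurably destroys the lesion
  signal; linear strided convolutions are a random-projection feature map that
  preserves it. The ResNet variant keeps ReLU because it is intended to carry
  pretrained weights.

Backbone weights are drawn from the run seed (He-normal) and frozen; a
user-supplied `.npz` can replace them (`backbone.weights_path`). Batch norms
start as the identity, which is exact for random-feature mode. Training never
updates the backbone (a config flag exists for fine-tuning but the loss is
defined on the decoders and fusion path).

### Edge path

EGM: F₁ is average-pool downsampled to F₂'s grid and 1×1-projected to F₂'s
width (average pooling avoids learnable aliasing in a pure alignment step).
The two concatenation orders each feed a learned 1×1 convolution with a single
output channel; the softmax is taken across the stacked {E₁, E₂} pair, so the
split weights are convex per position (E₁′+E₂′ = 1), and the fusion
E₁′⊗F₁′ ⊕ E₂′⊗F₂ broadcasts the scalar weights over feature channels — the
only reading under which the blend is well-typed after projection. The
"gated" 1×1 convolutions are plain learned convolutions; no extra
multiplicative gate is added.

EAM: squeeze-excitation channel attention (reduction 16 by default; 4 in the
tiny profile, where widths are small) re-weights the edge feature; average
pooling aligns it to F₄'s grid; a 3×3 convolution mixes the concatenation into
F_cat, and F_agg = GAP(F_cat)⊗F_cat ⊕ F₄. The residual form makes the whole
edge path an exact identity on F₄ when the mixing convolution is zero — the
ablated model is recovered continuously, which the tests assert bitwise.
F_agg replaces F₄ as the deepest flow input. For the aggregation-ablation
baselines, `edge.aggregation ∈ {eam, add, mul}`: add/mul run the pooled edge
feature through a zero-initialized 1×1 projection so they too start as the
identity.

### Flows

Each decoder stacks 8 affine coupling blocks (configurable `flow.depth`).
Per block: a fixed random channel permutation; split into halves; the
transformed half receives scale/shift predicted from the other half
concatenated with the condition field; the raw log-scale is soft-clamped via
`clamp · (2/π) · atan(raw/clamp)` with clamp 1.9; the log-determinant is the
per-position sum of clamped log-scales. The subnet is two 3×3 convolutions
(hidden width = input width, `flow.hidden_ratio`), the second zero-initialized
so every block starts as the identity (u = permuted z, log-det 0). The
condition is a fixed 2-D sinusoidal positional encoding (default 128 channels,
16 in the tiny profile; first half encodes the row, second half the column),
identical across batches. The implemented "forward" direction maps features to
the Gaussian base — the direction the loss needs; the inverse is evaluated
without the tape.

Loss per scale: L^k = mean over positions of ‖u‖²/2 − log|det J|. The additive
(d/2)·log 2π constant is dropped for optimization and restored wherever
normalized densities are required (scoring, quadrature tests). Per-scale
losses are summed with equal weights.

### Fusion

MFF pools the three shallow decoder outputs onto the deepest grid,
concatenates with the deepest output, applies two pointwise convolutions
(width-sum → width-sum/4 → width-sum; kernel size configurable via
`mff.kernel_size`, pointwise by default per the reference configuration even
though a 3×3 is also defensible), splits per scale, upsamples
(nearest-neighbour, preserving the residual identity exactly at zero
initialization) and adds residually. Pooling uses kernel 3 with stride
in/out and the smallest padding in {0, 1} that lands exactly on the target
side (padding 0 for 32→4 and 16→4, padding 1 for 8→4 — kernel 3/stride
2/padding 0 cannot reach 4 from 8); when kernel 3 does not fit (sub-kernel
grids in the tiny profile) the exact block average is used, since zero padding
would bias the mean.

The likelihood loss is computed on the **fused** outputs with each scale's
accumulated coupling log-determinant (`mff.loss_on = post_fusion`); the fusion
convolutions contribute no log-determinant. This is exact at initialization
(fusion is the identity) and an approximation afterwards: the convolutional
fusion is not invertible, so its exact contribution is intractable. The
residual zero-init structure keeps the approximation anchored; setting
`mff.loss_on = pre_fusion` computes the loss on the raw decoder outputs
instead.

### Scoring and metrics

Per position, log p = −‖u‖²/2 + log|det J| − (d/2)·log 2π. Pixel map:
per-scale negative log-densities upsampled bilinearly to input resolution and
summed. Image score: log-densities summed on the finest per-scale grid
(multiplicative aggregation of densities), negated, top-N mean (N = 100 at
256², 8 in the tiny profile; N is clipped to the map size with a warning).
Min-max normalization is used only for heat-map export, never for metrics.

Metrics: image/pixel AUROC (trapezoid, rank-averaged ties, via
scikit-learn); AUPRO as the exact per-region-overlap curve — at every distinct
threshold, the mean within-region TPR over 8-connected components of the
ground-truth masks versus the global FPR over all negative pixels of
mask-bearing images — integrated to an FPR cap of 0.3 (a community convention;
the cap is configurable and recorded in every report) and normalized by the
cap. Pixel precision/recall are reported at the F1-maximizing threshold on
the evaluated set, a deterministic and reproducible operating point chosen
because no canonical thresholding rule exists for this task.

## Phantom generator

Backgrounds are Gaussian-filtered white noise (correlation length
`texture_smoothness`, default 4 px) scaled to std 0.1 around mid-gray, plus
i.i.d. pixel noise (σ 0.02). Each abnormal image carries exactly one
elliptical lesion: semi-axes jittered in [0.7, 1.3] of half the sampled scale
fraction (default range 0.15–0.4 of the image side), random orientation and
placement (resampled to stay in bounds), signed contrast of magnitude
0.3–0.6 added inside a boundary profile blurred by `edge_blur_sigma`
(default 1.5 px) — the blurred-edge regime the edge path targets. Masks are
the pre-blur ellipses, saved as {0, 255} PNGs aligned with the images. The
default counts (40 train / 10 + 20 test at 64×64) mirror a small clinical
ultrasound corpus at reduced scale.

What the phantoms do **not** model: modality physics (speckle statistics,
beam hardening, bias fields), anatomy, multi-lesion images, acquisition
artifacts. Passing the phantom suites therefore demonstrates that the
pipeline detects blurred-edge intensity anomalies of variable scale on
correlated backgrounds — not clinical-grade performance.

## Problem sizes and numerics

Everything runs in float64 on a small in-package reverse-mode autodiff core
(`edgeflow.nn`); at the desk-scale grid sizes used here this is both fast and
numerically comfortable (flow round-trips are exact to ≤1e-5, analytic
log-determinants match finite differences to ≤1e-3). The desk-scale profile
(`RunConfig.tiny_test`) uses 64×64 images, the linear tiny backbone, condition
dimension 16, batch 8, 5 epochs of Adam at lr 1e-3 — a short schedule sized to
the 40-image phantom training set (25 optimizer steps), where the larger
learning rate replaces the reference schedule (lr 2e-4, batch 32, 100 epochs)
that the default configuration retains. The full 256×256 default model builds
and walks a dummy batch in a few seconds; the phantom train/evaluate cycle
takes a few seconds end to end.

Degenerate inputs: single-class metric inputs raise `UndefinedMetricError`;
empty latent fields, mismatched widths, non-square or non-divisible
resolutions, and unknown backbone/aggregation names raise configuration or
value errors; thresholds that predict nothing positive are rejected rather
than silently returning 0/0.

## Known limitations

- Random frozen backbones are a validated operating mode for the phantom
  suites but weaker than pretrained features on real images; pretrained
  weights must be supplied by the user as an `.npz`.
- The post-fusion likelihood ignores the fusion convs' (non-invertible)
  volume change; scores remain exact log-densities only of the per-scale
  flows' latents.
- Parameter counts depend on the coupling-subnet widths, which are a design
  choice (`flow.hidden_ratio`); the reported count is informational.
- AUPRO is exact but O(thresholds × regions); on very large test sets a
  subsampled threshold grid would be the natural extension.
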