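# Methods

This note records the modelling and numerical choices behind
`vesselseg`, in the order data flows through the pipeline.

## Preprocessing

RGB fundus photographs are collapsed to one channel with the BT.601
luminance weights (0.299, 0.587, 0.114) and round-half-away rounding;
green-channel extraction is available as `gray_method="green"` because
the green channel carries most vessel contrast in practice. CLAHE
follows the classic contrast-limited scheme in the OpenCV dialect: the
per-tile histogram is clipped at `clip × tile_area / 256` (default clip
10.0, 8×8 tile grid), the excess redistributed uniformly, the per-tile
CDF used as an intensity mapping, and pixel values blended bilinearly
between the four surrounding tile mappings. Edge tiles may be smaller
than interior tiles; different CLAHE dialects legitimately differ at
the bit level, so tests check properties (range, constancy, contrast
gain against scikit-image's implementation) rather than exact values.
Gamma correction is a global 8-bit lookup table `255·(v/255)^γ`;
the recipe's γ = 1.0 makes it the identity, which is also why the
"locally adaptive" refinement some preprocessing pipelines use is not
implemented: at γ = 1 every such scheme degenerates to the identity
anyway, and no concrete local formula is specified for other γ.
Normalisation to [0, 1] happens after all 8-bit steps.

## Augmentation and patching

The training-set expansion factors are fixed by the published dataset
sizes: 20 DRIVE images must become 1200 and 14 CHASE_DB1 images 1680.
The angle sets are not published, so the package uses uniform coverage
that reproduces the factors exactly: rotations at multiples of 12°
(30 angles) × horizontal mirror for DRIVE (60×), multiples of 6°
(60 angles) × mirror for CHASE_DB1 (120×). Rotation uses bilinear
interpolation with reflect padding for images and nearest-neighbour for
masks (preserving binarity). Patches are 64×64 with 100 patches per
augmented image (120,000/1200 and 168,000/1680 both force exactly 100);
because 100 evenly tiling patches fit neither image geometry, patch
positions are drawn uniformly over all fully contained top-left corners
(seeded). An optional field-of-view rejection filter
(`fov_min_frac`) exists but is off by default, matching the
unconditional sampling of the recipe. The 80/20 train/validation split
is a seeded shuffle with `|train| = round(0.8·N)`.

Inference slices a preprocessed image into a non-overlapping grid,
reflect-padding up to multiples of 64; stitching is row-major
reassembly plus a crop, an exact left inverse of slicing.

## Network

Layout NCHW over the in-package autodiff engine (`vesselseg.nn`:
reverse-mode tape on numpy arrays; convolutions via strided windows and
einsum; the 2×2-stride-2 transposed convolution specialises to a
non-overlapping einsum; gradients of every primitive are verified
against central differences in `tests/test_nn.py`). Double precision
throughout — CPU numpy gains little from float32 and bit-exact
determinism tests become trivial.

Choices the architecture description leaves open, and what this package
does:

* **Boundary refinement residual** — one k×k convolution with ReLU
  (not a two-convolution stack): the minimal reading of "R(·) is the
  convolution operation".
* **Attention normalisation** — the affinity matrices PS (position) and
  CS (channel) get a row softmax. Unnormalised (H·W)² products grow
  with feature magnitude and are numerically unstable; the ancestral
  dual-attention design normalises, and the add + batch-norm fusion
  replaces its learned scale.
* **ConvLSTM fusion order** — skip first, then the upsampled decoder
  map, from a zero initial state; the final hidden state is used.
* **MDASPP low branch** — 2×2 average pooling (replicate-padded when a
  spatial dim is odd), and bilinear resize back to the exact high-branch
  dims, so odd inputs round-trip; the dimension annotation that places
  X2_out at half resolution after upsampling is treated as a typo.
  MDASPP dropout is 0.2 (light regularisation; unspecified).
* **Decoder refinement** — two depthwise-separable convolutions at
  dilation 2 ("deep dilated convolution"); each encoder/decoder stage
  ends in batch norm. Dropout is inactive and batch norm uses moving
  statistics at inference, so inference is deterministic.
* **Ablation presets** — a1 = plain U-Net; a2 adds multiscale input,
  ConvLSTM fusion and the separable dilated decoder; a3 adds GCN+BR;
  a4 adds CA+PA; a5 adds MDASPP. The ladder-inclusion invariant is
  asserted on the enabled-feature sets (a5 *replaces* a4's plain
  bottleneck, so literal layer-name inclusion cannot hold there).

### Width calibration

The published per-layer widths are not printed, but two total
parameter counts are: 9,029,111 for the full model and 14,223,095 with
MDASPP ablated. `scripts/calibrate.py` therefore treats the stage
widths, multiscale-conv widths, plain-bottleneck width, MDASPP branch
width and the two dense growth rates as calibration knobs and solves
for both totals **exactly**, exploiting that the total is linear in
each multiscale width (a 3-variable linear Diophantine problem per
bottleneck width) and quadratic in the low-branch growth (closed-form
root). Among all exact solutions the script prefers the most
conventional knobs (widths doubling from 32, multiscale widths near the
stage widths, equal growths). The shipped defaults are its top-ranked
solution:

    widths (32, 64, 128, 256), ms_widths (32, 76, 69),
    bottleneck_width 642, mdaspp_branch 59, growths 17 / 15.

`count_from_config` (the analytic count the search uses) is unit-tested
to equal `count_params` of the actually built model on every preset.

## Training

Binary cross-entropy (probabilities clamped to [1e-7, 1-1e-7], clamping
logged), Adam, initial learning rate 0.1, ×0.1 on a validation-loss
plateau (patience 1 epoch, min-delta 1e-4 — the published rule names no
exact semantics), floor 1e-6 to avoid underflow, batch size 8 (DRIVE) /
16 (CHASE), checkpoint at the strict argmin of validation loss. Epoch
count is configurable (default 50; unspecified in the recipe).

One practical caveat the tests surface deliberately: Adam's step size is
≈ lr regardless of gradient magnitude, so lr 0.1 is only sensible when
an epoch contains thousands of updates (batch 8 over ~10⁵ patches). On
the reduced fixtures used in the test suite an epoch is 1–4 updates, so
the tiny-overfit test trains at lr 0.01 with plateau patience 10 — the
same rule, scaled to the fixture's updates-per-epoch — and reaches
≥0.95 training pixel accuracy on 8 synthetic patches within 100 epochs.

## Evaluation

Confusion counts are taken over the field-of-view mask when one is
supplied and over the full frame otherwise (the convention behind the
published numbers is unstated; FOV restriction is the stricter choice
and the CLI accepts `--fov`). Binarisation threshold 0.5. Metrics with
a zero denominator are reported as missing (`None`), never coerced to
0. AUC uses the trapezoidal area under the ROC curve
(scikit-learn); tests pin it to the O(n²) Mann–Whitney pairwise
statistic and to invariance under monotone score transforms.

## Synthetic data

The generator emulates the features of fundus photographs the pipeline
actually exercises: a circular field of view on a near-black frame, a
smooth low-frequency orange background texture, recursive branching
vessel trees (random-walk centerlines started on the FOV rim, ±20–60°
branch angles, length decay 0.7 per generation, width taper) rendered
darker than the background with the contrast concentrated in the green
channel, a 1-pixel bright centerline stripe as the reflex confound, and
additive Gaussian noise. Defaults (8 trees, root half-widths 1.5–4.5 px,
6 generations at the 584×565 DRIVE geometry) give a vessel density of
0.06–0.12 of the FOV across seeds, in the range of real fundus images.
Identical specs are bit-identical; dataset generation uses consecutive
seeds.

What it does **not** emulate: optic disc, fovea, exudates,
haemorrhages, inter-image illumination gradients, camera vignetting,
or realistic vessel tortuosity statistics. Passing tests therefore show
that the pipeline and optimisation behave correctly on images with
fundus-like low-level statistics — not that the published benchmark
metrics on DRIVE/CHASE_DB1 are reproduced, which would require the real
images and full-scale training (out of scope here; the acceptance
suite substitutes block-level oracle equivalence, the exact pipeline
integers, the exact parameter totals, a tiny-overfit check and an
end-to-end smoke run).

## Problem sizes in the test suite

Suites run on 1 CPU, so simulations are scaled down as the package's
own test design: 128×128 synthetic frames with proportionally thinner
and fewer vessels (density stays fundus-like), 32×32 training patches
(position attention's (H·W)² energy makes 64×64 training batches
memory-hungry; inference on 64×64 tiles uses the no-grad path),
reduced widths (8, 16, 32), and patch-count checks on 48×48 frames
with 8×8 patches — the expansion integers are content-independent.
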