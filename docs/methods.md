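# Methods

`paddycount` estimates rice plant density from RGB field images annotated
with one dot per plant root. Counting is cast as *blockwise classification*:
instead of regressing a local count for every image patch, the model
predicts which log-spaced *count interval* the patch falls in, which
flattens the extremely skewed distribution of patch counts (most patches are
empty or nearly so, a few are dense). This note records the model, the
numerical choices, and what the synthetic test bed does and does not show.

## Learning-target codec

**Density map.** The dot map `P` (1 at each annotated root pixel, with
multiplicity kept when two roots round to the same pixel) is convolved with
a 2-D Gaussian of standard deviation σ (default **4 px** at working
resolution). The kernel is truncated at 3σ and renormalized per dot over its
truncated, border-clipped support, so every dot contributes exactly unit
mass and `sum(density) == #dots` holds to 1e-6 regardless of dot placement.
Truncation and renormalization are our choices: without per-dot
renormalization, border dots lose mass and the counting chain is no longer
conservative.

**Count map.** Patch counts `N(b_j)` are sums of the density map over
square blocks (default **32 px**) placed at a stride (default **8 px**, so
16 patches overlap each interior pixel). Only fully contained patches are
emitted; the network pads inputs to a multiple of 32 so this never truncates
content. Ground-truth patch counts are computed on the density map, not the
raw dot map, so a plant near a patch boundary contributes fractionally to
both patches.

**Quantizer.** A positive count `n` maps to class
`max(floor((ln n − q)/s) + 2, 1)` capped at `c_max`; class 0 is reserved for
exactly-empty patches and class 1 for counts in `(0, e^q)`. Defaults
**s = 0.1, q = −2**. The logarithm is natural — the interval boundaries are
`e^{q+(c−2)s}`, which only makes sense in base e. `c_max` is not a free
constant: it is set at training time to the class of the largest training
patch count plus one, and stored in the checkpoint. Decoding maps a class to
the midpoint of its interval, `(Nt(c) + Nt(c+1))/2`, giving a worst-case
relative roundtrip error of `(e^s − 1)/2` (≈ 5.3% at s = 0.1) for any count
at or above `e^q`.

**Deredundancy.** Each predicted patch count is spread evenly over its
block's pixels and every pixel averages the contributions of the patches
covering it (dividing by the coverage count `T(x, y)`); the image total is
the sum of the resulting pixel count map. This decode is exactly
mass-conserving wherever coverage is uniform. Within roughly one block plus
one stride of the frame border, coverage drops and the averaging re-weights
patch contributions, which inflates totals when plant mass sits in that
band; this is a property of the decode itself, not of any model. The
synthetic generator therefore keeps root dots at least 48 px from the frame
edge (see below), and the conservation tests quantify the residual error
(≤ 0.05 plants per image at that margin).

## Network

A staged convolutional backbone is tapped at output strides 8/16/32. Each
top-down fusion step projects the deeper map to twice the channel width of
the shallower map (1×1 convolution + batch norm), upsamples it bilinearly
×2, concatenates the shallower map, and reduces back to `2·C2` channels with
a 1×1 convolution + batch norm + ReLU. The 2:1 channel ratio makes the
deeper, semantically stronger features dominate the fused representation;
the post-concatenation reduction keeps the documented `2H1 × 2W1 × 2C2`
output contract, which the pre-concatenation widths alone would not.
Fusing 1, 2 or 3 taps leaves the output at stride 32, 16 or 8.

The redundant head is unpadded average pooling whose kernel spans 32 input
pixels at the fused stride (4×4 at stride-8 features), followed by a 1×1
convolution to `c_max + 1` class logits and a softmax — one cell per 32×32
input patch at the fused stride, so an H×W input yields an
`(H/8 − 3) × (W/8 − 3)` class grid at the default three-layer fusion.
Argmax ties break toward the lower class index for determinism. The
regression ablation replaces the class projection with a single linear
output per patch, trained with an l1 loss and clamped at zero before
decoding.

Two backbones are built in. `tiny` is a small plain-conv pyramid (stride-4
stem, ≤64 channels) sized so a full training run fits in minutes on one CPU
core; it is the backbone every test uses. `mixnet` is a mixed-kernel
depthwise (MDConv) architecture in the MixNet family with taps at the same
strides; its exact block schedule is our own small instantiation rather than
a weight-compatible replica of a published variant, and weights can be
loaded from an `.npz` by name/shape match. All layers initialize with the
Xavier scheme from a seeded generator.

The whole network stack runs on a small reverse-mode autodiff engine
written on numpy (im2col + BLAS convolutions, float32 throughout) that
lives in `paddycount.nnkit`. It implements exactly the operations the
counter needs and is validated op-by-op with central-difference gradient
checks.

## Training

Images are brought to working resolution (1/4 of native by default; the
synthetic scenes are generated at working resolution, so their ratio is 1),
one random crop is drawn per image per epoch, and inputs are normalized by
training-set channel statistics. Optimization is SGD; the full-scale recipe
is lr 1e-2 divided by 10 every 200 epochs for 600 epochs, 384-px crops,
batch 8. Momentum 0.9 and weight decay 1e-4 are standard values, exposed in
the config. Crops are sampled uniformly over valid offsets from a fresh
seeded stream per epoch; images smaller than the crop are reflect-padded.
No flip or color augmentation is applied by default. Classification and
regression modes draw identical crops and share the pre-quantization count
targets, so the ablation isolates the learning target.

## Inference and metrics

Whole images are forwarded at once (fully convolutional): normalize, pad
right/bottom by reflection to a multiple of 32, forward, per-patch argmax,
midpoint dequantization, deredundancy, discard padded margins, sum.
Totals are real-valued; the CSV writer adds a rounded column.

Metrics: MAE, RMSE (the mean-square form without the root is available by
flag, but reported magnitudes follow the rooted definition), relative MAE as
the mean of per-image `|est − gt|/gt` in percent, and R² as the squared
Pearson correlation of ground-truth vs estimated totals (the
`1 − SS_res/SS_tot` definition is available by flag). rMAE is reported as
undefined when any ground-truth count is zero.

## Synthetic scenes

The generator emulates early-season flooded-paddy imagery at working
resolution: a greenish-brown water base with glint speckle and a linear
illumination ramp, plants rendered as radial clusters of 4–9 curved leaf
strokes with footprint radii 10–38 px, placed on a jittered row grid with a
minimum-separation constraint. `overlap_fraction` widens jitter and relaxes
separation (more entangled canopies); `reflection_noise` and
`illumination_gradient` scale the photometric nuisances. Everything is
drawn from a single seeded generator, so scenes are bitwise reproducible.
Root dots stay ≥ 48 px from the frame border so every plant's density mass
lies in the uniformly covered interior of the redundant grid (see
deredundancy above). Default scenes are 512×512; a `paper-like` preset
emits 1068×712 frames with counts in the hundreds.

What the generator does *not* model: real leaf texture and color
distributions, growth-stage appearance change, wind blur, specular water
reflections with structure, and plants truncated by the frame. Passing
tests on these scenes validates the encode/decode mathematics, the training
loop, and the relative merit of classification over regression at desk
scale — not field-ready accuracy on real imagery, which requires the full
recipe (a pretrained backbone, hundreds of high-resolution images, hundreds
of epochs).

## The desk-scale study

`paddycount.benchmark.run_study` fixes a small fully seeded protocol: 64
training and 16 held-out scenes of 256×256 px with 10–60 plants each, the
tiny backbone trained from scratch for 30 epochs (224-px crops, lr decayed
at epoch 20) in both classification and regression modes, scored with the
metric suite. Problem sizes were chosen so the whole study runs in a couple
of minutes on one CPU core while leaving enough signal to separate the two
modes; at seed 0 the classifier reaches rMAE ≈ 6% on held-out scenes and
beats the identically trained regression ablation (≈ 12%), reproducing the
direction of the full-scale comparison at a fraction of the scale.

## Numerical and degenerate-input choices

- Summed-area tables back the blockwise sums; tiny negative residues from
  cumulative-sum cancellation are clipped at zero.
- Out-of-bounds dots after rounding are clamped to the border with a
  warning; negative coordinates are an error.
- A zero channel standard deviation in normalization statistics is replaced
  by 1 with a warning.
- Grayscale inputs are replicated to three channels with a warning;
  zero-size images are an error.
- An overlapping count map refuses `total_count` and directs the caller to
  `deredundancy`.
- Non-finite training losses abort with the epoch, learning rate and batch
  statistics in the message.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; it is sized for the tiny
  backbone and desk-scale studies, not for full-resolution training of the
  mixnet backbone.
- No uncertainty accompanies the totals.
- The decode's border band (see above) means images whose plants extend to
  the frame edge will over-count slightly; tiling with overlap, or padding
  the scene, mitigates this.
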