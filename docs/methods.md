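# Methods

`entroseg` implements a patch-based pipeline for segmenting cerebral
aneurysms in 3D angiographic volumes.  The task is characterised by two
difficulties: extreme class imbalance (roughly 98% of voxels are
background) and the near-identical appearance of aneurysms and the vessels
they grow on.  The pipeline addresses the first with entropy-guided sampling
of training patches and the second with a gradient term that prefers
sharp-edged structures, a three-slice input that adds through-plane context,
and a recombination step at inference that restores foreground integrity at
patch borders.

## Preprocessing and sampling

Every slice `X_i` of a volume is min-max normalised to `[0, 255]`
(`(x - min)/(max - min) * 255`); a constant slice maps to all zeros, the
"no information" convention that also avoids division by zero.

**Slice selection.**  Within each block of 10 consecutive slices the 7 with
the highest *range entropy* are retained:

    RH(S) = H(S) + w * R(S)
    H(S)  = -sum_i p_i log2 p_i          (256 integer gray bins)
    R(S)  = (1/b) (sum max_b(S) - sum min_b(S))

with defaults `w = 0.05`, `b = 10`.  Histogram bins are obtained by rounding
to the nearest integer in `[0, 255]`, since the entropy sum runs over the
256 integer gray levels.  When the depth is not a multiple of the block
length, the leftover block keeps `ceil(7/10 * len)` slices (proportional
rule).  Ties rank by (score desc, z asc), so selection is deterministic.

**Patching.**  A `96x96` window slides over each slice with stride 32,
top-left to bottom-right, keeping only fully contained windows; a `256x256`
slice yields a 6x6 grid of 36 patches.

**Triplet selection.**  Candidate inputs are triplets of same-window patches
from three consecutive *retained* slices; the network predicts the centre
patch's mask.  Candidates are ranked by the centre patch's *gradient
entropy*

    GH(P) = H(P) + gamma * G_y(P)
    G_y(P) = (1/c) * sum of the c largest values of P(i,j) - P(i,j-1)

with `gamma = 0.1`, `c = 20`.  The column-difference index range is clipped
to `j = 1..W-1` (0-based), i.e. all in-bounds first differences, and the
differences are signed.  The top `top_k = 200` triplets per sample form the
training set.  Ranking is per volume; per-slice or global ranking would be a
one-line change but per-volume matches the "200 inputs per sample"
bookkeeping.  The first and last retained slices are never centres (no
padding is invented).  Aneurysm rims have larger local gradients than smooth
vessel walls, so the gradient bonus shifts the selected set toward
aneurysm-bearing windows without ever reading the labels.

**Augmentation.**  For every three consecutive slices of the volume one
window position is drawn and applied identically to all three, giving
`D//3` random-crop triplets; each crop yields one horizontally flipped and
one 45-degree rotated variant, so `3*(D//3)` (= `D` when 3 divides `D`)
additional inputs.  Rotation uses bilinear interpolation for intensities,
nearest-neighbour for masks, zero fill at the corners.  The crop window
reuses the patch size, as no separate crop size is specified anywhere.

## Network

The segmentation network is U-shaped with a Transformer bottleneck.

* **Encoder** — ResNet34-style: a 7x7 stride-2 stem, a 2x2 max-pool, and
  four layers of two-convolution residual blocks with counts 3/4/6/3 and
  widths `(w, 2w, 4w, 8w)`, `w = 64` by default.  "Bottleneck" block counts
  follow ResNet34, whose blocks are two-convolution basic blocks; a dropout
  (p = 0.2) sits after the second convolution of each block, before the
  residual addition.  Total stride 32: a `3x96x96` triplet maps to
  `512x3x3`.
* **Normalisation** — GroupNorm instead of BatchNorm inside the blocks.
  The package trains on CPU with small batches, where batch statistics are
  noisy and make evaluation depend on batch composition; GroupNorm gives
  batch-size-independent, deterministic behaviour at equal parameter count.
* **Bottleneck** — a 1x1 convolution (the linear projection) maps the
  feature map to `d = 512` tokens over the `N = 3x3` grid; a learnable
  `d x N` position embedding is added once; then `L` pre-norm Transformer
  layers: `c' = MHA(LN(c)) + c`, `c = FFN(LN(c')) + c'`.  Depth and head
  count are not fixed by the method; defaults are `L = 4`, 8 heads, FFN
  width `4d` (standard ViT ratios), all configurable.  For off-design input
  sizes the PE table is bilinearly resampled over the token grid.
* **Decoder** — five x2 nearest-upsampling stages with two-convolution
  blocks; the first four concatenate the resolution-matched encoder skip
  (layer 3, layer 2, layer 1, stem).  Concatenation was chosen over addition
  for skip fusion (channel counts differ level by level).  A final 1x1
  convolution emits two-class scores, softmaxed per pixel.

The network runs on a compact numpy reverse-mode autodiff engine
(`entroseg.nn`): conv2d via im2col, group/layer norm, multi-head attention,
Adam.  Gradients of every op are verified against central finite differences
in the test suite.

## Training

Softmax Dice loss on the foreground channel,
`1 - (2*sum(pg) + eps)/(sum(p) + sum(g) + eps)` with `eps = 1` (stabilises
empty targets; the background channel is implicit).  Adam at `lr0 = 1e-4`,
batch 32, 50 epochs; when the validation Dice has not improved by more than
`1e-6` for 15 epochs the learning rate is halved.  Validation Dice is the
hard Dice of patch predictions at threshold 0.5 — a cheap per-epoch signal;
the recombination pipeline is evaluated separately.  Splits are at volume
level (70/10/20), so no patch of one volume crosses splits.  Only
learning-rate decay is used; there is no early stopping.

## Inference and recombination

All slices are segmented (slice selection applies to training only); the
first/last slices use edge-replicated triplets.  Each slice's 36 windows are
predicted independently.  Rather than plain per-pixel averaging — which
blurs patch borders — the stitcher enumerates *coverage cases*: for one
six-patch row, the first and last windows are mandatory, any 2 of the 4
interior windows complete the cover (`C(4,2) = 6` cases), and the seventh
case uses all six with per-pixel averaging.  Each of the 6 pair cases is
verified programmatically to cover the 256-pixel extent.  A full-slice
configuration draws one case per row band and one per column band; the
row-wise and column-wise stitched maps are averaged, and a pixel covered by
several selected windows takes their mean.  The printed enumeration size for
this geometry is `6*7^4 + 7^3 = 14,749`; inference samples `n_samples = 49`
configurations uniformly at random (seeded) and averages them into `S_Aver`.

36 candidates are formed by overwriting one window of `S_Aver` with that
window's own prediction.  With `n` = the number of candidates whose
binarised map (threshold 0.5) contains any foreground, the slice is declared
positive when `S_Aver` has foreground and `n > eta` (`eta = 36 - 3 = 33`),
or when `S_Aver` is empty but `n > 36 - eta`; the candidate with the largest
foreground pixel count becomes the final mask (ties to the lowest window
index), otherwise the slice is declared aneurysm-free.  "Containing an
aneurysm" is read as any-foreground rather than connected-component
counting, consistent with the 0–36 scale of the threshold.  The plain
average strategy is kept as `average_stitch` for A/B comparison; both agree
exactly on constant inputs.  Grids other than 6x6 fall back to average
stitching with a warning — the case enumeration is specific to that
geometry.

## Evaluation

Dice, IoU, recall, precision, F2 (`5PR/(4P+R)`) with an explicit both-empty
convention (score 1, i.e. correct detection of absence; callers see the
count of such samples so aggregates are not silently inflated).  HD95 is
computed between mask boundaries (mask minus erosion) in 3D on the assembled
volume, directed distances per boundary voxel via KD-tree, 95th percentile
with linear interpolation, symmetrised by max, scaled by the voxel spacing
(0.5 mm default); it is undefined for empty masks and such samples are
excluded from the aggregate with a logged count.  mAP is the mean of the
exact average precision of the foreground class and of the background class
(scores and labels inverted), using every unique probability as a threshold;
an accuracy-style per-class precision would be the alternative reading, but
threshold-swept AP is the standard meaning of AP in segmentation.

## Synthetic phantoms

No public data ships with the package; the `phantom` module generates
volumes that reproduce the statistical regime the method assumes: ~220
contiguous 256x256 slices at isotropic 0.5 mm, bright tubular vessels
(background class), sphere-like aneurysms (foreground) attached to vessel
surface points, ~2% foreground, additive Gaussian noise.  Vessels are
random walks with bounded turning angle (radius 3–5 px, jittered per step);
aneurysms are spheres of radius 5–9 px (5–9 mm diameter at 0.5 mm voxels,
clinically plausible).  Both structures render at the same interior
intensity (200 vs background 30) with saturated lumina, so they cannot be
told apart by brightness — the confusability that motivates the gradient
term.  Aneurysm rims are blurred with a narrower Gaussian (sigma 0.5 voxels)
than vessel walls (sigma 0.9), encoding the assumption that aneurysms have
higher local gradients than vessels.  Noise sigma is 12 gray levels (~5% of
the dynamic range).  When `n_aneurysms` is unset it is derived from the
target foreground fraction and the mean sphere volume, topped up until the
fraction is within ±50% of target.

What the phantoms do *not* model: hemodynamics, contrast-agent dynamics,
reconstruction artefacts, anatomy-specific vessel trees, intensity
inhomogeneity.  Passing tests on phantoms demonstrate that the pipeline's
mechanics (sampling, learning, recombination, metrics) behave as specified,
not that the trained network transfers to clinical angiography.

## Problem sizes and numerical choices

Tests and the demo run at reduced scale on CPU: the demo uses four
12x256x256 phantoms with 2 aneurysms each, 24 triplets per volume, a
width-8 encoder with a single Transformer layer (the architecture is
unchanged, only narrower and shallower), ~160 Adam steps at `lr = 3e-3`,
then full recombination inference and evaluation on the training volumes.
The overfitting check trains the same reduced model on 8 triplets for at
most 200 steps.  Tie-breaks everywhere are deterministic; all randomness
(phantoms, splits, dropout, shuffling, configuration sampling) flows from
explicit seeds, and one global pipeline seed derives per-stage seeds.

Known limitations: the numpy engine is single-threaded apart from BLAS and
far slower than a GPU framework, so default-width training to convergence is
impractical here; the full-slice configuration count `6*7^4 + 7^3` is
reproduced as the stated enumeration size, while sampling draws independent
uniform row/column cases — the sampled family is what inference actually
uses; the covering reading of "C(4,2)+1 cases per row" is the only one
consistent with the count and with full coverage, but it is an
interpretation.
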