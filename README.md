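# entroseg

Entropy-guided, patch-based segmentation of cerebral aneurysms in 3D
angiographic volumes (DSA-like, 256x256 in-plane, isotropic 0.5 mm), with a
synthetic vascular phantom generator so the whole pipeline can be exercised
and tested without clinical data.

Aneurysm segmentation is hard for two reasons: about 98% of voxels are
background, and aneurysms look almost exactly like the vessels they grow
on.  `entroseg` implements a pipeline built around those two facts:

1. **Range-entropy slice selection** — of every 10 consecutive slices, keep
   the 7 with the highest `RH(S) = H(S) + w·R(S)`, where `H` is Shannon
   entropy over the 256 gray bins and `R` is a generalised range (mean of
   the top-*b* minus bottom-*b* gray values); defaults `w = 0.05`, `b = 10`.
2. **Gradient-entropy patch selection** — slide a 96x96 window with stride
   32 (36 patches per 256x256 slice) and rank candidate patches by
   `GH(P) = H(P) + γ·G_y(P)`, with `G_y` the mean of the top-*c* columnwise
   intensity differences (`γ = 0.1`, `c = 20`).  Aneurysm rims have sharper
   gradients than vessel walls, so the top 200 triplets per volume are
   enriched in aneurysm-bearing windows — without looking at the labels.
3. **A CNN–Transformer network** — three consecutive patches form a
   3-channel input (a 2D/3D compromise); a ResNet34-style encoder (block
   counts 3/4/6/3, dropout in each residual block) maps 3x96x96 to
   512 channels at 3x3, an L-layer pre-norm Transformer with learnable
   position embedding mixes the 9 tokens globally, and a skip-connected
   decoder restores the 96x96 centre-patch segmentation.
4. **Case-enumeration recombination** — at inference each slice's 36
   overlapping patch predictions are stitched by sampling 49 of the
   6·7⁴+7³ = 14,749 coverage configurations (7 cases per row/column band)
   and averaging them into `S_Aver`; 36 candidates overwrite one window each,
   and an η-threshold rule (η = 33) decides whether the slice contains an
   aneurysm and which candidate becomes the final mask.
5. **Metrics** — Dice, IoU, recall, precision, F2, threshold-swept mAP and
   the 95th-percentile Hausdorff distance in millimetres.

The network and its training loop run on a compact numpy reverse-mode
autodiff engine included in the package (`entroseg.nn`); gradients are
verified against finite differences in the test suite.

## Worked example

Everything is runnable from Python or the `entroseg` CLI.  A desk-scale
end-to-end run (4 small phantoms, reduced-width network, ~3 minutes on one
CPU):

```python
from entroseg.pipeline import PipelineConfig, run_demo

report = run_demo(PipelineConfig.demo_defaults(seed=1))
print(report.per_sample[["sample", "dice", "iou", "map"]])
```

prints (seed 1):

```
  sample      dice       iou       map
0   vol0  0.457396  0.296509  0.770367
1   vol1  0.428895  0.272989  0.666781
2   vol2  0.430879  0.274599  0.717560
```

Each row is one training phantom segmented by the freshly trained reduced
model through the full recombination pipeline: a Dice around 0.44 after ~160
optimisation steps of a width-8 network, against 0.002 for the untrained
network — the pipeline learns, at a scale that finishes on a laptop.  The
output directory also receives the predicted masks, the training history
CSV, a JSON-lines run log and `metrics.csv` with per-volume and aggregate
rows.

The same stages individually:

```bash
entroseg phantom --depth 24 --size 256 --n-aneurysms 2 --seed 1 \
    --out-image img.nii.gz --out-mask msk.nii.gz
entroseg preprocess --image img.nii.gz --mask msk.nii.gz --top-k 200 --out-dir trips/
entroseg train --data-dir trips/ --out ckpt.npz --seed 1
entroseg predict --image img.nii.gz --checkpoint ckpt.npz --eta 33 \
    --n-samples 49 --seed 1 --out-mask pred.nii.gz
entroseg evaluate --pred-mask pred.nii.gz --gt-mask msk.nii.gz --spacing 0.5
```

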