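# Methods

## Problem and pipeline

The package locates and counts small animals — bodies of roughly 1.5–2.5 m,
i.e. at most ~9 pixels in 0.38–0.50 m satellite imagery — in georeferenced
4-band (R, G, B, NIR) scenes, and turns the detections into census counts
and density products. An animal at this resolution is a 3–4 pixel long,
1–3 pixel wide dark blob with 1–2 darker center pixels; objects this small
defeat bounding-box detectors, so the pipeline works at the pixel level and
recovers individuals afterwards:

1. **Labeling & tiling.** Scenes are tiled into fixed-size patches
   (336 × 336 px in production, 150–170 m on the ground depending on
   resolution). Point annotations are fused across observers by majority
   voting and expanded to 3 × 3-pixel blocks to form binary masks.
2. **Segmentation.** A U-Net ensemble predicts per-pixel animal presence.
   The training set is split into K folds (K = 10 in production); base
   model *i* trains on all folds but *i* and validates on fold *i*. Member
   probability maps are min-max rescaled (when their maximum exceeds 0.05)
   and averaged.
3. **Individual recovery.** The fused map is thresholded at 0.5, connected
   components are extracted (8-connectivity), and each component of *n*
   pixels is split into ceil(*n* / 9) individuals by K-means on pixel
   coordinates; cluster centroids are the detected points.

Evaluation is per individual: predictions and references are matched
one-to-one within a radius equal to the diagonal of one pixel
(√2 × 0.5 m ≈ 0.71 m), giving TP/FP/FN and precision/recall/F1; PR curves
add the conventional endpoints (recall 0, precision 1) and (1, 0) and use
composite-trapezoid AUC.

## Model and loss

The U-Net is the classic symmetric encoder–decoder: `depth` levels of two
3 × 3 ReLU convolutions and 2 × 2 max pooling, a bottleneck, and a mirrored
expanding path (nearest-neighbor upsampling, a halving convolution, skip
concatenation, two convolutions), closed by a 1 × 1 convolution and
sigmoid. Defaults are depth 4 with 64 base filters doubling per level;
weights are He-normal, dropout defaults to 0.

Animal pixels are <1% of the data, so training uses the Tversky loss with
soft counts,

    L = 1 − (TP + s) / (TP + α·FP + β·FN + s),   α + β = 1,

with `fp_weight` α = 0.1 and `fn_weight` β = 0.9 by default — the weighting
that favors recall of animal pixels — and stabilizer `s = 1`. At
α = β = 0.5 the loss reduces to Dice (with stabilizer 2s), which the tests
verify numerically. We name the parameters by their function
(`fp_weight`/`fn_weight`) rather than by Greek letters, because the α/β
naming convention is ambiguous across the literature; the defaults
reproduce the intended asymmetry (penalize missed animals 9× more than
false alarms).

During optimization the loss is evaluated **per sample** and averaged over
the batch — the canonical formulation for Dice-family losses. Pooling the
soft counts across a whole batch instead makes each sample's gradient
share one global denominator; empirically that conditioning is poor enough
that individual ensemble members can stall in the early uniform-probability
phase of training. The exported ``tversky_loss`` function keeps the plain
soft-count definition for arbitrary arrays.

The network and its training loop are implemented directly on numpy:
convolutions evaluate as BLAS matrix products (an im2col product during
training, reused for the weight gradient; shifted per-tap products at
inference), gradients are hand-derived (and checked against float64
references in the tests), and optimization is Adam. The full-scale schedule is learning rate 1e-4, batch
12, 120 epochs, learning rate × 0.33 after a 20-epoch validation plateau,
with the minimum-validation-loss checkpoint kept. One integer seed drives
initialization, shuffling and fold assignment, so runs are bit-reproducible
on a fixed thread count.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `patch_px` | 336 | tile side in pixels; 168 m at 0.5 m GSD |
| `mask block` | 3 × 3 px | rasterized footprint of one point label |
| `fp_weight`, `fn_weight` | 0.1, 0.9 | Tversky error penalties (sum to 1) |
| `K` | 10 | ensemble folds/members |
| `rescale_threshold` | 0.05 | max-probability gate for member min-max rescaling |
| `prob_threshold` | 0.5 | binarization threshold on the fused map |
| `connectivity` | 8 | segment connectivity (diagonal 3–4 px bodies fragment under 4) |
| `object_size_px` | 9 | typical animal footprint; ceiling-division unit |
| `radius` | √2 × pixel size | point-matching radius (0.71 m at 0.5 m) |
| `cell_size`, `radius` (density) | 100 m, 500 m | hotspot raster definition |
| bit-depth ceiling | 2¹¹ − 1 | fixed radiometric normalization divisor |

Normalization divides raw counts by the sensor bit-depth ceiling rather
than stretching per image, keeping radiometry consistent between training
and inference. Binarization treats ties at the threshold as positive.
K-means uses seeded k-means++ with 10 restarts. Matching processes
candidate pairs globally by increasing distance with a stable index
tie-break — deterministic, order-independent, and equal to the optimal
assignment whenever references are farther than twice the radius apart
(verified against a Hungarian oracle). Count uncertainty over repeated
trainings uses a t-interval (appropriate at n = 5); a normal-approximation
flag exists for comparison.

## Synthetic scenes

Real sub-meter imagery of this kind is proprietary, so the
`wildcount.synthetic` module generates seeded stand-in scenes for testing
and benchmarking: 11-bit 4-band rasters with a low-frequency background
texture; animals rendered as rotated dark ellipses within the stated size
ranges (3–4 × 1–3 px, 1–2 darker center pixels, default contrast 0.45);
aggregation patterns scattered (uniform with minimum separation), linear
(jittered points along a random trail), or clustered (parent–offspring
Thomas process); and confuser objects — NIR-bright bushes, elongated dark
mound shadows larger than any animal, bright road strips and dark river
bands. A reference-pair generator emits two scenes sharing background and
confusers with animals in only one, mirroring the cross-date
disambiguation workflow used during labeling.

These scenes exercise every pipeline contract, but they are deliberately
not photorealistic: no sensor PSF/MTF, no atmospheric or illumination
variation, no real vegetation texture, and confusers that are cleanly
separable in shape or spectrum. Passing the synthetic benchmark therefore
demonstrates that the machinery (loss, ensemble, post-processing,
evaluation) works end-to-end; it does not predict accuracy on real
imagery, where background clutter is far harder.

## Scaled-down benchmark

`wildcount.experiment.synthetic_end_to_end` runs the whole pipeline at
sizes chosen for a single CPU core: a depth-3 U-Net with 8 base filters
on 96 × 96 patches, a K = 3 ensemble, 192 training patches (~8
well-separated, high-contrast animals plus a bush and a mound shadow per
patch), a 20-epoch schedule at Adam's standard 1e-3 rate (the 1e-4 /
120-epoch schedule belongs to full-scale runs) with the standard ×4
flip/rotation augmentation, and 50 held-out tiles (~400 animals). The
benchmark reports point-matching precision/recall/F1 at the 0.71 m radius
and PR-AUC for the ensemble and each member, on a coarse 0.1-step
threshold sweep. The epoch count is the main runtime dial: the preset's
full schedule is 20 epochs, the test suite runs 14 and the acceptance
script 10 to bound their single-core wall times; the validation loss is
essentially converged from roughly epoch 6 on, so these schedules differ
mainly in how sharply the members suppress confuser objects.

## Numerical and degenerate-case choices

- World coordinates refer to pixel centers; windows are half-open and
  0-based; round-tripping integer pixel centers is exact.
- Border tiles are zero-padded to the patch size for inference and cropped
  back; they are excluded from training sampling.
- Member-map rescaling is per inference window; a constant map above the
  0.05 gate has no defined rescale and is zeroed with a warning.
- Density stratification uses breakpoints μ, μ+σ, μ+2σ on per-cell counts;
  with σ = 0 every cell is assigned the medium stratum.
- A PR sweep defaults to thresholds 0.05…0.95 in steps of 0.05; AUC sorts
  points by recall with ties ordered by descending precision so vertical
  segments have zero width.
- Overlap-free tiling can split an object straddling a seam into two
  detections; maps are stitched before post-processing, which reconnects
  most seam-crossing segments, and the remaining behavior (1–2 points) is
  documented and tested.

## Known limitations

- The numpy training engine is single-process and CPU-bound; full-scale
  (336 px, depth 4, K = 10, 120 epochs) training is out of reach without a
  GPU framework, which is why the benchmark preset is scaled down.
- Synthetic-scene realism bounds what the benchmark can claim (above).
- Species discrimination among similar-sized ungulates is beyond the
  imagery's resolution and out of scope.
- Observer-skill modeling is not attempted; label fusion is plain majority
  voting with complete-linkage clustering at the matching radius.
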