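# prosthvis

Optimized visual-information presentation for simulated prosthetic vision.

Retinal implants stimulate the visual pathway through a small electrode
array — tens to a few thousand electrodes against ~1.3 million ganglion
cells — so the wearer perceives a scene as a coarse grid of *phosphenes*
(spots of light). Rendering a raw camera frame at that resolution destroys
most of the information needed to recognize objects. `prosthvis` implements
an image-processing chain that spends the few available phosphenes on the
object of interest instead of background clutter, together with the
simulation and evaluation tools needed to study it:

1. **Salient-object detection** by two-stage manifold ranking on a SLIC
   superpixel graph. With affinity matrix `W`, degree matrix `D` and a binary
   query vector `y`, the ranking is

   `f = (1 − α) (D − αW)⁻¹ y,   α ∈ (0, 1)`.

   Stage one uses the superpixels on each image border as background queries
   (boundary prior) and fuses the four side maps by pointwise product; stage
   two thresholds that map at its mean and re-ranks with the surviving nodes
   as foreground queries.
2. **Mask segmentation** by dual (hysteresis) thresholds — Otsu for the high
   threshold, half of it for the low one — with connected-component analysis
   and morphological cleanup.
3. **Presentation strategies** built on multiscale Sobel edges (3×3 and 7×7
   kernels fused by pointwise geometric mean):
   - **FEBR** — foreground edge detection + background reduction: object
     contours at intensity 255 over a background linearly halved into 0–127;
   - **FZE** — foreground zoom + edge detection: the object's minimal
     bounding box is rescaled to fill the field, the background removed, and
     the zoomed foreground edge-detected.
4. **Phosphene rendering (LRG, Lowering Resolution with Gaussian dots)** —
   the image is block-averaged to an N×N grid and each value drawn as a
   Gaussian luminance dot `I(x,y) = A·exp(−((x−uₓ)² + (y−u_y)²)/2σ²)`,
   swept over the resolutions 8, 16, 24, 32, 48, 64 by default.

Evaluation utilities provide precision/recall/F-measure (with the
benchmark weighting β² = 0.3) and the 0/1/2 recognition-score normalization
RA = RS/2 × 100%. A deterministic synthetic-scene generator supplies images
with exact ground-truth masks, so the whole chain is testable without any
external dataset.

## Worked example

```python
from prosthvis import scenes, saliency, segmentation, metrics, strategies, phosphenes

spec = scenes.SceneSpec(seed=11)          # 320x320 disc on cluttered background
image, truth = scenes.generate_scene(spec)

field, _, _ = saliency.detect_salient_object(image)
mask, thresholds = segmentation.segment_saliency(field.pixel_map)
print(f"hysteresis thresholds: t_low={thresholds.t_low:.3g}  t_high={thresholds.t_high:.3g}")
print(f"IoU vs ground truth: {metrics.iou(mask, truth):.3f}")
scores = metrics.prf(mask, truth)
print(f"precision={scores.precision:.3f}  recall={scores.recall:.3f}  F={scores.f_measure:.3f}")

percept = phosphenes.lrg(strategies.febr(image, mask), 32)
print(f"32x32 percept: peak={percept.raster.max():.0f}  sigma={percept.grid.sigma:.2f} px")
```

prints

```
hysteresis thresholds: t_low=0.000977  t_high=0.00195
IoU vs ground truth: 0.999
precision=0.999  recall=1.000  F=0.999
32x32 percept: peak=65  sigma=1.67 px
```

The tiny thresholds reflect how cleanly the two-stage ranking separates this
high-contrast scene: background scores collapse toward zero, so Otsu places
the cut just above them. The recovered mask matches the exact ground truth
almost pixel-for-pixel; the final line is the FEBR percept a 32×32 implant
would deliver (tile means of a sparse 255-valued edge image, hence the
peak of 65).

The same chain is available from a shell:

```
prosthvis fixtures --n 20 --seed 7 --out fixtures/
prosthvis run fixtures/scene_000.png --strategy febr --resolution all --out out/
prosthvis eval predicted_masks/ truth_masks/ --csv report.csv
```

`run` writes every stage artifact (saliency maps, mask, strategy output, one
percept per resolution) plus `manifest.json` with parameters and SHA-256
checksums; a rerun with the same config and seed is bitwise identical.

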