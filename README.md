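# rbcdetect

Detection and counting of red blood cells (RBCs) in microscopy images.
Stained blood smears show RBCs as roughly circular, often touching or
overlapping discs, darker than the surrounding plasma; counting and
localizing them is the basis of complete-blood-count style analysis, and
doing it by hand is slow and error-prone. `rbcdetect` provides a compact,
fully tested pipeline for this problem, aimed at method developers who
want every stage verifiable against exact ground truth.

The package contains:

- **Synthetic scenes** (`rbcdetect.synthetic`) — blood-smear-like fields of
  elliptical cells with touching clusters, background gradient and
  Gaussian + speckle noise, each carrying its exact instance mask and
  bounding boxes, so every downstream stage is testable without any
  external data.
- **Edge-preserving filtering** (`rbcdetect.filters`) — a bilateral filter

  `I'(i,j) = Σ_pq w(i,j,p,q) I(p,q) / W(i,j)`, with
  `w = exp(−((i−p)² + (j−q)²) / 2σ_d²) · exp(−(I(i,j) − I(p,q))² / 2σ_r²)`,

  applied iteratively until convergence, plus the radial gradient index
  (RGI): the mean cosine between local intensity gradients and the outward
  radial direction over a disc — ≈ +1 for a radially symmetric dark-center
  blob, ≈ 0 on background.
- **Threshold + morphology segmentation** (`rbcdetect.segment`) — Otsu or
  fixed threshold splits the image into foreground `F` (`I ≤ T`, dark
  cells) and background `B`; the result mask is
  `R = 1 iff dilate(F) = 1 and erode(B) = 0`, followed by 8-connected
  component counting with a minimum-area gate.
- **A desk-scale region-proposal detector** (`rbcdetect.detector`) —
  anchors on a stride lattice → box-regression decode → border clipping →
  size filter → score sort with `pre_nms_topN` → greedy NMS with
  `post_nms_topN` → RoI max-pooling → classification + box refinement
  heads trained with a multitask loss (cross-entropy + smooth-L1). The
  feature extractor is a fixed bank of Gaussian / Laplacian-of-Gaussian /
  gradient kernels matched to the anchor scales; the heads are linear
  models trained from scratch with a small Adam loop — CPU-only,
  seed-reproducible, no pretrained weights.
- **Post-processing** (`rbcdetect.postprocess`) — per-region scoring
  (detector score, center-disc RGI, box-counting fractal dimension),
  weighted ranking, and RGI-based false-positive filtering.
- **Evaluation** (`rbcdetect.evaluation`) — greedy IoU matching,
  precision / recall / F1 / detection accuracy `TP/(TP+FP+FN)`, and
  60/20/20 holdout or 10-fold cross-validation split plans.
- **Augmentation** (`rbcdetect.augment`) — random affine warps (rotation,
  shifts, shear, zoom, horizontal flip, intensity rescale 1/255) applied
  consistently to images and their boxes.

The filtering, segmentation, augmentation and detection stages are exposed
as scikit-learn-style estimators (`BilateralFilter`, `ThresholdSegmenter`,
`RandomAugmenter`, `RBCDetector`) with `fit`/`transform`/`predict` and
`get_params`/`set_params`, alongside plain functions for the individual
operations.

## Worked example

```python
import numpy as np
from rbcdetect import (SceneParams, generate_scene, generate_scenes,
                       ThresholdSegmenter, FilterParams, iterate_filter,
                       RBCDetector, match_detections, compute_metrics)
from rbcdetect.evaluation import MatchResult

# 1. A noisy 256x256 smear field with 20 cells, filtered and counted.
scene = generate_scene(SceneParams(n_cells=20, noise_sigma=0.05, seed=0))
filtered, n_iter = iterate_filter(scene.image,
                                  FilterParams(sigma_d=1.5, sigma_r=0.1, n_iterations=3))
count, regions = ThresholdSegmenter(min_area=30).count(filtered)
print(f"filter iterations used: {n_iter}")
print(f"segmented cell count:   {count} (truth: {scene.n_cells})")

# 2. Train the region detector on 200 small scenes, evaluate on 50 held out.
params = SceneParams(image_height=64, image_width=64, n_cells=5, radius_range=(5, 9),
                     eccentricity_range=(0.0, 0.3), overlap_fraction=0.2,
                     noise_sigma=0.02, background_gradient=0.05)
train, test = generate_scenes(params, 200, seed=1000), generate_scenes(params, 50, seed=9000)
model = RBCDetector(random_state=0).fit(train)
tp = fp = fn = 0
for s in test:
    m = match_detections(model.predict(s.image), s.boxes, iou_threshold=0.5)
    tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
metrics = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn))
print(f"detector precision={metrics['precision']:.3f} recall={metrics['recall']:.3f} "
      f"f1={metrics['f1']:.3f} (IoU 0.5, 50 held-out scenes)")
```

Output:

```
filter iterations used: 3
segmented cell count:   20 (truth: 20)
detector precision=0.960 recall=0.960 f1=0.960 (IoU 0.5, 50 held-out scenes)
```

The segmentation chain recovers the exact cell count despite the noise,
and the detector localizes 96% of held-out cells at IoU 0.5 with 96%
precision after about ten seconds of CPU training.

## Command line

```sh
rbcdetect simulate --config scene.yaml --out data/ --n-images 50 --seed 0
rbcdetect filter   --in img.png --out filtered.png --sigma-d 1.5 --sigma-r 0.1 --iters 3
rbcdetect segment  --in img.png --out mask.png --threshold otsu --min-area 30
rbcdetect augment  --in data/ --out augmented/ --n-per-image 4 --seed 0
rbcdetect train    --data data/ --config cfg.yaml --out model.npz --seed 0
rbcdetect detect   --model model.npz --in img.png --out detections.csv --mask mask.png
rbcdetect evaluate --pred detections.csv --truth boxes.csv --iou 0.5 --out metrics.json
```

Detections are CSV (`image,x0,y0,x1,y1,score,label`, half-open 0-based
boxes), instance masks 16-bit PNG, model checkpoints versioned `.npz`.

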