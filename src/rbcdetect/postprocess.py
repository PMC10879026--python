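"""Post-network refinement of raw detections.

Three optional stages run after the detector: per-region scoring (detector
confidence, radial gradient index at the region center, box-counting
fractal dimension of the thresholded patch), ranking by a weighted
combination of min-max-normalized components, and an RGI filter that drops
regions whose gradients are not radially organized around the center.

The box-counting (Minkowski-Bouligand) dimension is used as a plausibility
feature only: round solid cells fill their patch (dimension near 2) while
thin or speckly artifacts trace curves (near 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Detection
from .filters import radial_gradient_index
from .segment import select_threshold

__all__ = ["RegionScore", "fractal_dimension", "score_regions", "rgi_region_filter"]


@dataclass
class RegionScore:
    """Component scores and combined rank score for one detection."""

    detection: Detection
    detector_score: float
    rgi: float
    fractal: float
    area: float
    combined: float = 0.0


def fractal_dimension(mask_patch: np.ndarray) -> float:
    """Box-counting dimension of a binary patch.

    The patch is padded into the smallest enclosing power-of-two square and
    counted with dyadic boxes of side 1, 2, ..., side/2; the estimate is the
    least-squares slope of ``log N(s)`` against ``log (1/s)``, clipped to
    ``[0, 2]``. A patch whose box count cannot vary (single pixel, or a
    canvas too small for two box sizes) scores 0. An empty patch raises.
    """
    patch = np.asarray(mask_patch)
    if patch.ndim != 2:
        raise ValueError("expected a 2-D binary patch")
    patch = patch > 0
    if not patch.any():
        raise ValueError("empty patch has no box-counting dimension")
    side = 1
    while side < max(patch.shape):
        side *= 2
    canvas = np.zeros((side, side), dtype=bool)
    canvas[: patch.shape[0], : patch.shape[1]] = patch
    sizes = []
    counts = []
    s = 1
    while s <= side // 2:
        reduced = canvas.reshape(side // s, s, side // s, s).any(axis=(1, 3))
        sizes.append(s)
        counts.append(int(reduced.sum()))
        s *= 2
    if len(sizes) < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def _region_patch_mask(image: np.ndarray, det: Detection) -> np.ndarray:
    m, n = image.shape
    x0 = int(np.clip(np.floor(det.box[0]), 0, n))
    y0 = int(np.clip(np.floor(det.box[1]), 0, m))
    x1 = int(np.clip(np.ceil(det.box[2]), 0, n))
    y1 = int(np.clip(np.ceil(det.box[3]), 0, m))
    patch = image[y0:y1, x0:x1]
    if patch.size == 0:
        return np.zeros((1, 1), dtype=np.uint8)
    try:
        T = select_threshold(patch, "otsu")
    except ValueError:  # constant patch
        T = float(patch.flat[0])
    return (patch <= T).astype(np.uint8)


def score_regions(
    image: np.ndarray,
    detections: list[Detection],
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1),
) -> list[RegionScore]:
    """Score and rank detections.

    Per detection: RGI over the center disc of radius half the smaller box
    side, fractal dimension of the dark-thresholded patch, and the detector
    score, combined as a weighted sum of min-max-normalized components
    ``(detector, rgi, fractal)``. Returns the list ranked best-first;
    ties keep input order.
    """
    image = np.asarray(image, dtype=float)
    if not detections:
        return []
    records = []
    for det in detections:
        radius = max(1.0, 0.5 * min(det.width, det.height))
        rgi = radial_gradient_index(image, det.center, radius)
        patch_mask = _region_patch_mask(image, det)
        fd = fractal_dimension(patch_mask) if patch_mask.any() else 0.0
        records.append(RegionScore(det, det.score, rgi, fd, det.area))
    det_n = _minmax(np.array([r.detector_score for r in records]))
    rgi_n = _minmax(np.array([r.rgi for r in records]))
    fd_n = _minmax(np.array([r.fractal for r in records]))
    wd, wr, wf = weights
    for r, a, b, c in zip(records, det_n, rgi_n, fd_n):
        r.combined = float(wd * a + wr * b + wf * c)
    order = np.argsort([-r.combined for r in records], kind="stable")
    return [records[i] for i in order]


def rgi_region_filter(
    image: np.ndarray, detections: list[Detection], rgi_threshold: float = 0.3
) -> list[Detection]:
    """Keep detections whose center-disc RGI reaches the threshold.

    Order is preserved; the output is always a subset of the input, so the
    operation is idempotent.
    """
    image = np.asarray(image, dtype=float)
    kept = []
    for det in detections:
        radius = max(1.0, 0.5 * min(det.width, det.height))
        if radial_gradient_index(image, det.center, radius) >= rgi_threshold:
            kept.append(det)
    return kept
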