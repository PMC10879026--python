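"""Axis-aligned bounding boxes and the :class:`Detection` record.

Boxes are half-open ``[x0, x1) x [y0, y1)`` in 0-based pixel coordinates,
stored as ``(x0, y0, x1, y1)``. A degenerate (zero-area) box has IoU 0 with
everything, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection",
    "box_area",
    "box_iou_matrix",
    "clip_boxes",
    "detections_to_array",
    "array_to_detections",
]


@dataclass
class Detection:
    """A scored, labelled bounding box.

    Attributes
    ----------
    box : tuple of float
        ``(x0, y0, x1, y1)``, half-open pixel coordinates.
    score : float
        Foreground probability in ``[0, 1]``.
    label : str
        Class tag, ``"rbc"`` or ``"background"``.
    """

    box: tuple[float, float, float, float]
    score: float = 1.0
    label: str = "rbc"
    extras: dict = field(default_factory=dict)

    @property
    def width(self) -> float:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> float:
        return self.box[3] - self.box[1]

    @property
    def area(self) -> float:
        return max(0.0, self.width) * max(0.0, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.box[0] + self.box[2]), 0.5 * (self.box[1] + self.box[3]))


def box_area(boxes: np.ndarray) -> np.ndarray:
    """Area of ``(N, 4)`` boxes; negative extents count as zero."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    w = np.clip(boxes[:, 2] - boxes[:, 0], 0.0, None)
    h = np.clip(boxes[:, 3] - boxes[:, 1], 0.0, None)
    return w * h


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union between two box sets.

    Parameters
    ----------
    a, b : ndarray
        ``(N, 4)`` and ``(M, 4)`` half-open boxes.

    Returns
    -------
    ndarray
        ``(N, M)`` IoU values; rows/columns of degenerate boxes are 0.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0.0, None) * np.clip(y1 - y0, 0.0, None)
    area_a = box_area(a)[:, None]
    area_b = box_area(b)[None, :]
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def clip_boxes(boxes: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Clamp box coordinates to ``[0, width] x [0, height]``.

    ``image_shape`` is ``(height, width)`` in the numpy convention.
    """
    m, n = image_shape
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    boxes[:, 0] = np.clip(boxes[:, 0], 0.0, n)
    boxes[:, 2] = np.clip(boxes[:, 2], 0.0, n)
    boxes[:, 1] = np.clip(boxes[:, 1], 0.0, m)
    boxes[:, 3] = np.clip(boxes[:, 3], 0.0, m)
    return boxes


def detections_to_array(detections: list[Detection]) -> tuple[np.ndarray, np.ndarray]:
    """Split a detection list into an ``(N, 4)`` box array and an ``(N,)`` score array."""
    if len(detections) == 0:
        return np.zeros((0, 4)), np.zeros((0,))
    boxes = np.array([d.box for d in detections], dtype=float)
    scores = np.array([d.score for d in detections], dtype=float)
    return boxes, scores


def array_to_detections(
    boxes: np.ndarray, scores: np.ndarray | None = None, label: str = "rbc"
) -> list[Detection]:
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    if scores is None:
        scores = np.ones(boxes.shape[0])
    return [
        Detection(box=tuple(float(v) for v in b), score=float(s), label=label)
        for b, s in zip(boxes, scores)
    ]
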