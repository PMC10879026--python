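"""Desk-scale region-based cell detector.

The detection pipeline follows the classical region-proposal recipe:

1. tile reference anchors over a stride lattice;
2. score each anchor and regress box corrections (RPN head);
3. clip decoded boxes to the image;
4. drop boxes below a minimum size;
5. sort by score and keep the top ``pre_nms_topN``;
6. greedy non-maximum suppression, then keep the top ``post_nms_topN``;
7. pool a fixed-size feature grid from each surviving region (RoI pooling);
8. classify each region and refine its box (RoI head), trained with a
   multi-task loss (classification cross-entropy + smooth-L1 localization);
9. per-class NMS and score thresholding produce the final detections.

The feature extractor is a fixed, deterministic bank of convolutional
kernels — Gaussian smoothing, scale-normalized Laplacian-of-Gaussian
responses matched to the anchor scales (a blob detector), and Gaussian
derivative/gradient channels — and the RPN/RoI heads are linear models on
those features, trained from scratch on synthetic scenes with a small Adam
loop. Everything is CPU-only and reproducible from a single seed.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_gradient_magnitude, gaussian_laplace
from sklearn.base import BaseEstimator

from .boxes import Detection, box_iou_matrix, clip_boxes, detections_to_array
from .filters import radial_gradient_index

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSpec",
    "ProposalConfig",
    "DetectionFilterConfig",
    "RBCDetector",
    "generate_anchors",
    "encode_boxes",
    "decode_boxes",
    "filter_proposals",
    "nms",
    "roi_pool",
    "smooth_l1",
    "multitask_loss",
    "train_detector",
    "detect",
    "filter_detections",
    "label_cells",
]


@dataclass
class AnchorSpec:
    """Anchor lattice: one anchor per (cell, scale, ratio).

    ``scales`` are box side lengths in pixels at ratio 1; a ratio ``r``
    stretches the box to width ``s * sqrt(r)`` and height ``s / sqrt(r)``,
    preserving area.
    """

    stride: int = 8
    scales: tuple[float, ...] = (12.0, 20.0, 32.0)
    ratios: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if len(self.scales) == 0 or len(self.ratios) == 0:
            raise ValueError("scales and ratios must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


@dataclass
class ProposalConfig:
    """Proposal filtering/suppression settings."""

    pre_nms_topN: int = 6000
    post_nms_topN: int = 300
    min_size: float = 8.0
    nms_iou: float = 0.7

    def __post_init__(self) -> None:
        if self.post_nms_topN > self.pre_nms_topN:
            raise ValueError("post_nms_topN must be <= pre_nms_topN")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must lie in (0, 1)")


@dataclass
class DetectionFilterConfig:
    """False-detection filter applied before labeling.

    A detection survives when its score is at least ``score_threshold``,
    the radial gradient index over its center disc is at least
    ``rgi_threshold`` (checked only when an image is supplied), and its
    area lies within ``area_range`` times the median detected area.
    """

    score_threshold: float = 0.5
    rgi_threshold: float = 0.0
    area_range: tuple[float, float] = (0.25, 4.0)


# ---------------------------------------------------------------------------
# Geometry primitives


def generate_anchors(image_shape: tuple[int, int], spec: AnchorSpec | None = None) -> np.ndarray:
    """Tile anchors over the stride lattice of an ``(m, n)`` image.

    Returns ``(A, 4)`` boxes with ``A = ceil(m/stride) * ceil(n/stride) *
    len(scales) * len(ratios)``, ordered lattice-cell-major then scale then
    ratio. Anchors may extend beyond the image before clipping.
    """
    spec = spec or AnchorSpec()
    m, n = image_shape
    hf = -(-m // spec.stride)
    wf = -(-n // spec.stride)
    cy = (np.arange(hf) + 0.5) * spec.stride
    cx = (np.arange(wf) + 0.5) * spec.stride
    shapes = []
    for s in spec.scales:
        for r in spec.ratios:
            shapes.append((s * np.sqrt(r), s / np.sqrt(r)))
    shapes = np.array(shapes)  # (K, 2) widths/heights
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (L, 2)
    L, K = centers.shape[0], shapes.shape[0]
    ctr = np.repeat(centers, K, axis=0)
    wh = np.tile(shapes, (L, 1))
    return np.concatenate([ctr - wh / 2.0, ctr + wh / 2.0], axis=1)


def encode_boxes(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Regression targets ``(tx, ty, tw, th)`` mapping anchors onto boxes."""
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2.0
    ay = anchors[:, 1] + ah / 2.0
    gw = boxes[:, 2] - boxes[:, 0]
    gh = boxes[:, 3] - boxes[:, 1]
    gx = boxes[:, 0] + gw / 2.0
    gy = boxes[:, 1] + gh / 2.0
    return np.stack(
        [(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def decode_boxes(anchors: np.ndarray, regression: np.ndarray) -> np.ndarray:
    """Apply ``(tx, ty, tw, th)`` corrections to anchors.

    Center moves by ``t * anchor size``; width/height scale by ``exp(t)``.
    All-zero coefficients reproduce the anchors exactly.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    regression = np.asarray(regression, dtype=float).reshape(-1, 4)
    if regression.shape[0] != anchors.shape[0]:
        raise ValueError("need one regression 4-tuple per anchor")
    if not np.all(np.isfinite(regression)):
        raise ValueError("non-finite regression coefficients")
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2.0
    ay = anchors[:, 1] + ah / 2.0
    x = ax + regression[:, 0] * aw
    y = ay + regression[:, 1] * ah
    w = aw * np.exp(regression[:, 2])
    h = ah * np.exp(regression[:, 3])
    return np.stack([x - w / 2.0, y - h / 2.0, x + w / 2.0, y + h / 2.0], axis=1)


def filter_proposals(
    boxes: np.ndarray,
    scores: np.ndarray,
    image_shape: tuple[int, int],
    config: ProposalConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clip, size-filter, and score-sort proposals.

    Coordinates are clamped to ``[0, width] x [0, height]``; boxes whose
    clipped width or height falls below ``min_size`` are removed; the rest
    are sorted by descending score (ties keep original order) and the top
    ``pre_nms_topN`` are returned.
    """
    config = config or ProposalConfig()
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).ravel()
    if boxes.shape[0] != scores.shape[0]:
        raise ValueError("boxes and scores length mismatch")
    if boxes.shape[0] == 0:
        return boxes, scores
    boxes = clip_boxes(boxes, image_shape)
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    keep = (w >= config.min_size) & (h >= config.min_size)
    boxes, scores = boxes[keep], scores[keep]
    order = np.argsort(-scores, kind="stable")[: config.pre_nms_topN]
    return boxes[order], scores[order]


def nms(
    boxes: np.ndarray,
    scores: np.ndarray,
    iou_threshold: float,
    post_nms_topN: int | None = None,
) -> np.ndarray:
    """Greedy non-maximum suppression.

    Accept the highest-scoring box, discard boxes whose IoU with any
    accepted box exceeds ``iou_threshold``, repeat; finally keep the top
    ``post_nms_topN`` accepted boxes. Returns indices into the input,
    in descending score order (ties by original index).
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).ravel()
    if boxes.shape[0] == 0:
        return np.zeros((0,), dtype=int)
    order = np.argsort(-scores, kind="stable")
    iou = box_iou_matrix(boxes, boxes)
    suppressed = np.zeros(boxes.shape[0], dtype=bool)
    keep: list[int] = []
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(int(idx))
        suppressed |= iou[idx] > iou_threshold
    if post_nms_topN is not None:
        keep = keep[:post_nms_topN]
    return np.array(keep, dtype=int)


def roi_pool(
    feature_map: np.ndarray, rois: np.ndarray, output_size: tuple[int, int] | int
) -> np.ndarray:
    """Max-pool each RoI into a fixed ``output_size`` grid.

    ``feature_map`` is ``(H, W)`` or ``(H, W, C)``; ``rois`` are ``(N, 4)``
    boxes in feature-map coordinates. Each RoI is rounded outward to whole
    cells, divided into an ``(oh, ow)`` grid of bins, and the maximum is
    taken over each bin. Degenerate bins yield 0.
    """
    fm = np.asarray(feature_map, dtype=float)
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[..., None]
    H, W, C = fm.shape
    rois = np.asarray(rois, dtype=float).reshape(-1, 4)
    if isinstance(output_size, int):
        oh = ow = output_size
    else:
        oh, ow = output_size
    out = np.zeros((rois.shape[0], oh, ow, C))
    for k, (x0, y0, x1, y1) in enumerate(rois):
        xi0 = int(np.clip(np.floor(x0), 0, W))
        yi0 = int(np.clip(np.floor(y0), 0, H))
        xi1 = int(np.clip(np.ceil(x1), 0, W))
        yi1 = int(np.clip(np.ceil(y1), 0, H))
        if xi1 <= xi0 or yi1 <= yi0:
            logger.debug("roi_pool: degenerate RoI %s after quantization; emitting zeros", (x0, y0, x1, y1))
            continue
        xe = np.floor(np.linspace(xi0, xi1, ow + 1)).astype(int)
        ye = np.floor(np.linspace(yi0, yi1, oh + 1)).astype(int)
        for bi in range(oh):
            for bj in range(ow):
                ys, ye_ = ye[bi], ye[bi + 1]
                xs, xe_ = xe[bj], xe[bj + 1]
                if ye_ > ys and xe_ > xs:
                    out[k, bi, bj] = fm[ys:ye_, xs:xe_].reshape(-1, C).max(axis=0)
    return out[..., 0] if squeeze else out


def smooth_l1(x: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Huber-style smooth-L1: ``0.5 x^2 / beta`` for ``|x| < beta`` else ``|x| - beta/2``."""
    x = np.abs(np.asarray(x, dtype=float))
    return np.where(x < beta, 0.5 * x**2 / beta, x - 0.5 * beta)


def multitask_loss(
    cls_scores: np.ndarray,
    cls_targets: np.ndarray,
    box_preds: np.ndarray,
    box_targets: np.ndarray,
    positive_mask: np.ndarray,
    lambda_loc: float = 1.0,
    beta: float = 1.0,
) -> float:
    """Classification cross-entropy plus weighted smooth-L1 localization.

    ``cls_scores`` are ``(N, K)`` class probabilities; the localization
    term is the smooth-L1 of the box error summed over the 4 coordinates
    and averaged over positive samples (zero when there are none).
    """
    cls_scores = np.asarray(cls_scores, dtype=float)
    cls_targets = np.asarray(cls_targets, dtype=int).ravel()
    positive_mask = np.asarray(positive_mask, dtype=bool).ravel()
    if cls_scores.shape[0] == 0:
        raise ValueError("no samples")
    p_true = np.clip(cls_scores[np.arange(cls_scores.shape[0]), cls_targets], 1e-12, 1.0)
    cls_loss = float(-np.mean(np.log(p_true)))
    if np.any(positive_mask):
        err = np.asarray(box_preds, dtype=float)[positive_mask] - np.asarray(box_targets, dtype=float)[positive_mask]
        loc_loss = float(np.mean(np.sum(smooth_l1(err, beta), axis=1)))
    else:
        loc_loss = 0.0
    return cls_loss + lambda_loc * loc_loss


# ---------------------------------------------------------------------------
# Feature bank

#: Gaussian-derivative scales for the gradient channels.
_GRAD_SIGMAS = (1.5, 3.0)

#: Minimum IoU for the forced best-anchor-per-truth positive assignment.
_MIN_FORCED_IOU = 0.1


def compute_feature_stack(image: np.ndarray, scales: tuple[float, ...]) -> np.ndarray:
    """Fixed convolutional feature bank, ``(H, W, C)``.

    Channels: Gaussian-smoothed intensity; one scale-normalized
    Laplacian-of-Gaussian per anchor scale (sigma = scale / (2 sqrt 2),
    matched to a disc of that diameter — responds positively at dark blob
    centers); Gaussian x/y derivatives at two scales (encode sub-stride
    offsets to the nearest blob); gradient magnitude; and a wide local mean.
    """
    image = np.asarray(image, dtype=float)
    chans = [gaussian_filter(image, 1.0)]
    for s in scales:
        sigma = s / (2.0 * np.sqrt(2.0))
        chans.append(sigma**2 * gaussian_laplace(image, sigma))
    for sigma in _GRAD_SIGMAS:
        chans.append(sigma * gaussian_filter(image, sigma, order=(0, 1)))  # d/dx
        chans.append(sigma * gaussian_filter(image, sigma, order=(1, 0)))  # d/dy
    chans.append(gaussian_gradient_magnitude(image, 1.0))
    chans.append(gaussian_filter(image, 4.0))
    return np.stack(chans, axis=-1)


def _lattice_features(stack: np.ndarray, stride: int) -> np.ndarray:
    """Sample the feature stack at anchor centers; returns ``(L, C)``."""
    H, W, _ = stack.shape
    hf = -(-H // stride)
    wf = -(-W // stride)
    ys = np.minimum((np.arange(hf) * stride + stride // 2), H - 1)
    xs = np.minimum((np.arange(wf) * stride + stride // 2), W - 1)
    return stack[np.ix_(ys, xs)].reshape(hf * wf, stack.shape[2])


class _Adam:
    """Minimal Adam optimizer over a dict of numpy arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.05):
        self.params = params
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# The estimator

_CHECKPOINT_VERSION = 1


class RBCDetector(BaseEstimator):
    """Region-proposal cell detector trained on ground-truth scenes.

    ``fit`` takes a sequence of :class:`~rbcdetect.synthetic.GroundTruthScene`
    (or ``(image, boxes)`` pairs) and trains the RPN and RoI heads;
    ``predict`` runs the full nine-step pipeline on one image and returns a
    list of :class:`~rbcdetect.boxes.Detection`.

    Parameters
    ----------
    stride, scales, ratios : anchor lattice (see :class:`AnchorSpec`).
    pre_nms_topN, post_nms_topN, min_size, nms_iou : proposal filtering
        (see :class:`ProposalConfig`).
    rpn_pos_iou, rpn_neg_iou : float
        Anchor target assignment: anchors with IoU >= ``rpn_pos_iou`` to a
        truth box (or the best anchor per truth) are positive, anchors with
        IoU <= ``rpn_neg_iou`` negative, the rest ignored.
    roi_pos_iou, roi_neg_iou : float
        Same for RoI-head proposal labelling.
    lambda_loc : float
        Localization weight in the multitask loss.
    score_threshold : float
        Final detection threshold on the RoI-head foreground probability.
    final_nms_iou : float
        IoU threshold of the per-class NMS on refined boxes.
    n_steps_rpn, n_steps_roi, learning_rate : optimization budget.
    random_state : int
        Seed for all internal sampling; fixed seed gives bit-identical
        training trajectories.

    Attributes
    ----------
    rpn_score_w_, rpn_box_w_ : learned RPN head weights.
    roi_cls_w_, roi_box_w_ : learned RoI head weights.
    loss_history_ : dict with per-step "rpn" and "roi" loss trajectories.
    """

    def __init__(
        self,
        stride: int = 8,
        scales: tuple[float, ...] = (12.0, 20.0, 32.0),
        ratios: tuple[float, ...] = (1.0,),
        pre_nms_topN: int = 6000,
        post_nms_topN: int = 300,
        min_size: float = 8.0,
        nms_iou: float = 0.7,
        rpn_pos_iou: float = 0.7,
        rpn_neg_iou: float = 0.3,
        roi_pos_iou: float = 0.5,
        roi_neg_iou: float = 0.3,
        lambda_loc: float = 1.0,
        score_threshold: float = 0.5,
        final_nms_iou: float = 0.3,
        roi_output_size: int = 6,
        roi_stride: int = 2,
        n_steps_rpn: int = 500,
        n_steps_roi: int = 400,
        learning_rate: float = 0.05,
        neg_pos_ratio: float = 3.0,
        random_state: int = 0,
    ):
        self.stride = stride
        self.scales = scales
        self.ratios = ratios
        self.pre_nms_topN = pre_nms_topN
        self.post_nms_topN = post_nms_topN
        self.min_size = min_size
        self.nms_iou = nms_iou
        self.rpn_pos_iou = rpn_pos_iou
        self.rpn_neg_iou = rpn_neg_iou
        self.roi_pos_iou = roi_pos_iou
        self.roi_neg_iou = roi_neg_iou
        self.lambda_loc = lambda_loc
        self.score_threshold = score_threshold
        self.final_nms_iou = final_nms_iou
        self.roi_output_size = roi_output_size
        self.roi_stride = roi_stride
        self.n_steps_rpn = n_steps_rpn
        self.n_steps_roi = n_steps_roi
        self.learning_rate = learning_rate
        self.neg_pos_ratio = neg_pos_ratio
        self.random_state = random_state

    # -- configuration helpers -------------------------------------------

    def _anchor_spec(self) -> AnchorSpec:
        return AnchorSpec(stride=self.stride, scales=tuple(self.scales), ratios=tuple(self.ratios))

    def _proposal_config(self) -> ProposalConfig:
        return ProposalConfig(
            pre_nms_topN=self.pre_nms_topN,
            post_nms_topN=self.post_nms_topN,
            min_size=self.min_size,
            nms_iou=self.nms_iou,
        )

    @property
    def _n_anchor_types(self) -> int:
        return len(self.scales) * len(self.ratios)

    #: channel indices of the fine map used for RoI pooling:
    #: smoothed intensity, middle LoG, gradient magnitude.
    def _fine_channels(self) -> list[int]:
        s = len(self.scales)
        return [0, 1 + s // 2, 1 + s + 2 * len(_GRAD_SIGMAS)]

    # -- data preparation -------------------------------------------------

    @staticmethod
    def _as_pairs(scenes) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for item in scenes:
            if hasattr(item, "image") and hasattr(item, "boxes"):
                boxes, _ = detections_to_array(item.boxes)
                pairs.append((np.asarray(item.image, dtype=float), boxes))
            else:
                image, boxes = item
                if boxes and isinstance(boxes[0], Detection):
                    boxes, _ = detections_to_array(boxes)
                pairs.append((np.asarray(image, dtype=float), np.asarray(boxes, dtype=float).reshape(-1, 4)))
        return pairs

    def _assign_anchor_targets(
        self, anchors: np.ndarray, gt: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-anchor label (1/0/-1 = pos/neg/ignore) and regression target."""
        A = anchors.shape[0]
        labels = np.zeros(A, dtype=int)
        targets = np.zeros((A, 4))
        if gt.shape[0] == 0:
            return labels, targets
        iou = box_iou_matrix(anchors, gt)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        labels[:] = -1
        labels[best_iou <= self.rpn_neg_iou] = 0
        labels[best_iou >= self.rpn_pos_iou] = 1
        # Guarantee a positive anchor per truth box, but only when the best
        # anchor overlaps it meaningfully; otherwise the configured scales
        # simply cannot represent the object.
        per_gt_best = iou.max(axis=0)
        for g in range(gt.shape[0]):
            if per_gt_best[g] >= _MIN_FORCED_IOU:
                labels[np.flatnonzero(iou[:, g] == per_gt_best[g])] = 1
        pos = labels == 1
        best_gt[pos] = iou[pos].argmax(axis=1)
        targets[pos] = encode_boxes(anchors[pos], gt[best_gt[pos]])
        return labels, targets

    # -- training ----------------------------------------------------------

    def fit(self, scenes, y=None):
        rng = np.random.default_rng(self.random_state)
        pairs = self._as_pairs(scenes)
        if not pairs or all(b.shape[0] == 0 for _, b in pairs):
            raise ValueError("need at least one training image with at least one box")
        spec = self._anchor_spec()
        K = self._n_anchor_types

        feats, kidxs, labels, targets = [], [], [], []
        stacks = []
        for image, gt in pairs:
            stack = compute_feature_stack(image, tuple(self.scales))
            stacks.append(stack)
            lat = _lattice_features(stack, self.stride)  # (L, C)
            anchors = generate_anchors(image.shape, spec)
            lab, tgt = self._assign_anchor_targets(anchors, gt)
            feats.append(np.repeat(lat, K, axis=0))
            kidxs.append(np.tile(np.arange(K), lat.shape[0]))
            labels.append(lab)
            targets.append(tgt)
        X = np.concatenate(feats)
        kidx = np.concatenate(kidxs)
        y_anchor = np.concatenate(labels)
        t_anchor = np.concatenate(targets)

        n_pos = int(np.sum(y_anchor == 1))
        if n_pos == 0:
            raise ValueError(
                "no positive anchors at the configured scales/stride; "
                "adjust `scales` to match the object sizes"
            )

        self.feature_mean_ = X.mean(axis=0)
        self.feature_std_ = X.std(axis=0) + 1e-8
        Xs = (X - self.feature_mean_) / self.feature_std_
        Xs = np.concatenate([Xs, np.ones((Xs.shape[0], 1))], axis=1)  # bias
        C1 = Xs.shape[1]

        # Subsample negatives for class balance (deterministic under seed).
        neg_idx = np.flatnonzero(y_anchor == 0)
        max_neg = int(self.neg_pos_ratio * n_pos)
        if neg_idx.size > max_neg:
            drop = rng.choice(neg_idx, size=neg_idx.size - max_neg, replace=False)
            y_anchor = y_anchor.copy()
            y_anchor[drop] = -1
        use = y_anchor >= 0
        pos_mask = y_anchor == 1

        params = {"ws": np.zeros((K, C1)), "wb": np.zeros((K, 4, C1))}
        opt = _Adam(params, lr=self.learning_rate)
        rpn_losses = []
        Xu, ku, yu = Xs[use], kidx[use], y_anchor[use].astype(float)
        Xp, kp, tp = Xs[pos_mask], kidx[pos_mask], t_anchor[pos_mask]
        n_use, n_p = Xu.shape[0], Xp.shape[0]
        for _ in range(self.n_steps_rpn):
            z = np.einsum("nc,nc->n", Xu, params["ws"][ku])
            p = 1.0 / (1.0 + np.exp(-z))
            tpred = np.einsum("nc,ndc->nd", Xp, params["wb"][kp])
            err = tpred - tp
            cls_loss = -np.mean(yu * np.log(np.clip(p, 1e-12, 1)) + (1 - yu) * np.log(np.clip(1 - p, 1e-12, 1)))
            loc_loss = float(np.mean(np.sum(smooth_l1(err), axis=1))) if n_p else 0.0
            rpn_losses.append(cls_loss + self.lambda_loc * loc_loss)
            dz = (p - yu) / n_use
            gws = np.zeros_like(params["ws"])
            np.add.at(gws, ku, Xu * dz[:, None])
            gwb = np.zeros_like(params["wb"])
            if n_p:
                derr = self.lambda_loc * np.clip(err, -1.0, 1.0) / n_p
                np.add.at(gwb, kp, derr[:, :, None] * Xp[:, None, :])
            opt.step({"ws": gws, "wb": gwb})
        self.rpn_score_w_ = params["ws"]
        self.rpn_box_w_ = params["wb"]

        # ---- RoI head: label proposals from the trained RPN ----
        roi_X, roi_y, roi_t = [], [], []
        train_cfg = ProposalConfig(
            pre_nms_topN=min(self.pre_nms_topN, 1000),
            post_nms_topN=min(self.post_nms_topN, 60),
            min_size=self.min_size,
            nms_iou=self.nms_iou,
        )
        for (image, gt), stack in zip(pairs, stacks):
            boxes, scores = self._rpn_proposals(image, stack, train_cfg)
            # Jittered truth boxes guarantee clean positives.
            if gt.shape[0]:
                jitter = rng.normal(scale=1.5, size=(2 * gt.shape[0], 4))
                extra = np.repeat(gt, 2, axis=0) + jitter
                boxes = np.concatenate([boxes, clip_boxes(extra, image.shape), gt])
            if boxes.shape[0] == 0:
                continue
            pooled = self._pooled_features(stack, boxes)
            if gt.shape[0]:
                iou = box_iou_matrix(boxes, gt)
                best = iou.argmax(axis=1)
                best_iou = iou.max(axis=1)
            else:
                best = np.zeros(boxes.shape[0], dtype=int)
                best_iou = np.zeros(boxes.shape[0])
            lab = np.full(boxes.shape[0], -1)
            lab[best_iou >= self.roi_pos_iou] = 1
            lab[best_iou <= self.roi_neg_iou] = 0
            tgt = np.zeros((boxes.shape[0], 4))
            posm = lab == 1
            if np.any(posm):
                tgt[posm] = encode_boxes(boxes[posm], gt[best[posm]])
            keep = lab >= 0
            roi_X.append(pooled[keep])
            roi_y.append(lab[keep])
            roi_t.append(tgt[keep])
        Xr = np.concatenate(roi_X)
        yr = np.concatenate(roi_y).astype(float)
        tr = np.concatenate(roi_t)
        n_rpos = int(yr.sum())
        if n_rpos == 0:
            raise ValueError("RoI head found no positive proposals; detector cannot be trained")
        neg_idx = np.flatnonzero(yr == 0)
        max_neg = int(self.neg_pos_ratio * n_rpos)
        if neg_idx.size > max_neg:
            keep_neg = rng.choice(neg_idx, size=max_neg, replace=False)
            sel = np.concatenate([np.flatnonzero(yr == 1), keep_neg])
            Xr, yr, tr = Xr[sel], yr[sel], tr[sel]

        self.roi_mean_ = Xr.mean(axis=0)
        self.roi_std_ = Xr.std(axis=0) + 1e-8
        Xrs = (Xr - self.roi_mean_) / self.roi_std_
        Xrs = np.concatenate([Xrs, np.ones((Xrs.shape[0], 1))], axis=1)
        D1 = Xrs.shape[1]
        posr = yr == 1
        params = {"wc": np.zeros(D1), "wr": np.zeros((4, D1))}
        opt = _Adam(params, lr=self.learning_rate)
        roi_losses = []
        Xp, tp = Xrs[posr], tr[posr]
        n_p = Xp.shape[0]
        for _ in range(self.n_steps_roi):
            z = Xrs @ params["wc"]
            p = 1.0 / (1.0 + np.exp(-z))
            tpred = Xp @ params["wr"].T
            err = tpred - tp
            cls_loss = -np.mean(yr * np.log(np.clip(p, 1e-12, 1)) + (1 - yr) * np.log(np.clip(1 - p, 1e-12, 1)))
            loc_loss = float(np.mean(np.sum(smooth_l1(err), axis=1))) if n_p else 0.0
            roi_losses.append(cls_loss + self.lambda_loc * loc_loss)
            dz = (p - yr) / yr.size
            gwc = Xrs.T @ dz
            gwr = np.zeros_like(params["wr"])
            if n_p:
                derr = self.lambda_loc * np.clip(err, -1.0, 1.0) / n_p
                gwr = derr.T @ Xp
            opt.step({"wc": gwc, "wr": gwr})
        self.roi_cls_w_ = params["wc"]
        self.roi_box_w_ = params["wr"]
        self.loss_history_ = {"rpn": rpn_losses, "roi": roi_losses}
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------

    def _rpn_proposals(
        self, image: np.ndarray, stack: np.ndarray, config: ProposalConfig
    ) -> tuple[np.ndarray, np.ndarray]:
        K = self._n_anchor_types
        lat = _lattice_features(stack, self.stride)
        Xs = (np.repeat(lat, K, axis=0) - self.feature_mean_) / self.feature_std_
        Xs = np.concatenate([Xs, np.ones((Xs.shape[0], 1))], axis=1)
        kidx = np.tile(np.arange(K), lat.shape[0])
        z = np.einsum("nc,nc->n", Xs, self.rpn_score_w_[kidx])
        scores = 1.0 / (1.0 + np.exp(-z))
        deltas = np.einsum("nc,ndc->nd", Xs, self.rpn_box_w_[kidx])
        anchors = generate_anchors(image.shape, self._anchor_spec())
        boxes = decode_boxes(anchors, deltas)
        boxes, scores = filter_proposals(boxes, scores, image.shape, config)
        keep = nms(boxes, scores, config.nms_iou, config.post_nms_topN)
        return boxes[keep], scores[keep]

    def _pooled_features(self, stack: np.ndarray, boxes: np.ndarray) -> np.ndarray:
        fine = stack[:: self.roi_stride, :: self.roi_stride, self._fine_channels()]
        pooled = roi_pool(fine, boxes / self.roi_stride, self.roi_output_size)
        return pooled.reshape(boxes.shape[0], -1)

    def predict(self, image: np.ndarray) -> list[Detection]:
        """Detect cells in one image (deterministic in eval mode)."""
        image = np.asarray(image, dtype=float)
        if min(image.shape) < self.stride:
            raise ValueError(
                f"image of shape {image.shape} is smaller than one stride ({self.stride})"
            )
        stack = compute_feature_stack(image, tuple(self.scales))
        boxes, _ = self._rpn_proposals(image, stack, self._proposal_config())
        if boxes.shape[0] == 0:
            return []
        pooled = self._pooled_features(stack, boxes)
        Xrs = (pooled - self.roi_mean_) / self.roi_std_
        Xrs = np.concatenate([Xrs, np.ones((Xrs.shape[0], 1))], axis=1)
        p = 1.0 / (1.0 + np.exp(-(Xrs @ self.roi_cls_w_)))
        refined = decode_boxes(boxes, Xrs @ self.roi_box_w_.T)
        refined = clip_boxes(refined, image.shape)
        ok = (refined[:, 2] - refined[:, 0] > 1) & (refined[:, 3] - refined[:, 1] > 1)
        refined, p = refined[ok], p[ok]
        keep = nms(refined, p, self.final_nms_iou)
        refined, p = refined[keep], p[keep]
        above = p >= self.score_threshold
        return [
            Detection(box=tuple(float(v) for v in b), score=float(s), label="rbc")
            for b, s in zip(refined[above], p[above])
        ]

    # -- persistence -------------------------------------------------------

    _WEIGHT_ATTRS = (
        "rpn_score_w_",
        "rpn_box_w_",
        "roi_cls_w_",
        "roi_box_w_",
        "feature_mean_",
        "feature_std_",
        "roi_mean_",
        "roi_std_",
    )

    def save(self, path: str) -> None:
        """Write a versioned ``.npz`` checkpoint (weights + constructor params)."""
        arrays = {name: getattr(self, name) for name in self._WEIGHT_ATTRS}
        arrays["__version__"] = np.array(_CHECKPOINT_VERSION)
        arrays["__params__"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "RBCDetector":
        data = np.load(path)
        version = int(data["__version__"])
        if version != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        params = json.loads(bytes(data["__params__"]).decode())
        for key in ("scales", "ratios", "area_range"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        model = cls(**params)
        for name in cls._WEIGHT_ATTRS:
            setattr(model, name, data[name])
        return model


# ---------------------------------------------------------------------------
# Module-level wrappers


def train_detector(scenes, config: dict | None = None, seed: int = 0) -> RBCDetector:
    """Train an :class:`RBCDetector`; ``config`` overrides constructor params."""
    model = RBCDetector(random_state=seed, **(config or {}))
    return model.fit(scenes)


def detect(
    model: RBCDetector,
    image: np.ndarray,
    config: ProposalConfig | None = None,
    score_threshold: float | None = None,
) -> list[Detection]:
    """Run the trained detector on one image."""
    if config is not None or score_threshold is not None:
        model = copy.deepcopy(model)
    if config is not None:
        model.set_params(
            pre_nms_topN=config.pre_nms_topN,
            post_nms_topN=config.post_nms_topN,
            min_size=config.min_size,
            nms_iou=config.nms_iou,
        )
    if score_threshold is not None:
        model.set_params(score_threshold=score_threshold)
    return model.predict(image)


def filter_detections(
    detections: list[Detection],
    config: DetectionFilterConfig | None = None,
    image: np.ndarray | None = None,
) -> list[Detection]:
    """Remove false detections by score, center-disc RGI, and relative area.

    The RGI criterion is evaluated on the supplied image over a disc of
    radius half the box's smaller side; it is skipped when no image is
    given. The area gate is relative to the median area of the input
    detections.
    """
    config = config or DetectionFilterConfig()
    if not detections:
        return []
    areas = np.array([d.area for d in detections])
    median_area = float(np.median(areas))
    kept = []
    for det in detections:
        if det.score < config.score_threshold:
            continue
        if median_area > 0:
            rel = det.area / median_area
            if not (config.area_range[0] <= rel <= config.area_range[1]):
                continue
        if image is not None:
            radius = max(1.0, 0.5 * min(det.width, det.height))
            if radial_gradient_index(image, det.center, radius) < config.rgi_threshold:
                continue
        kept.append(det)
    return kept


def label_cells(
    image_shape: tuple[int, int],
    detections: list[Detection],
    filter_config: DetectionFilterConfig | None = None,
    image: np.ndarray | None = None,
) -> np.ndarray:
    """Binary label mask: the set union of the surviving detection boxes.

    Pixels inside any filtered detection's (half-open, rounded) box are 1.
    """
    if filter_config is not None:
        detections = filter_detections(detections, filter_config, image)
    m, n = image_shape
    mask = np.zeros((m, n), dtype=np.uint8)
    for det in detections:
        x0 = int(np.clip(np.round(det.box[0]), 0, n))
        y0 = int(np.clip(np.round(det.box[1]), 0, m))
        x1 = int(np.clip(np.round(det.box[2]), 0, n))
        y1 = int(np.clip(np.round(det.box[3]), 0, m))
        mask[y0:y1, x0:x1] = 1
    return mask
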