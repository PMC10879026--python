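"""Detection evaluation: IoU matching, metrics, and split protocols.

Predictions are matched to truth boxes greedily in descending score order;
each prediction takes the highest-IoU still-unmatched truth with IoU at or
above the threshold. Precision, recall, F1 and a detection "accuracy"
TP / (TP + FP + FN) are reported. Split plans cover both a 60/20/20
train/validation/test holdout and k-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boxes import Detection, box_iou_matrix, detections_to_array

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "SplitPlan", "match_detections", "compute_metrics", "make_splits"]

DEFAULT_IOU_THRESHOLD = 0.5


@dataclass
class MatchResult:
    """Outcome of matching one prediction set against one truth set."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, truth, IoU)


@dataclass
class SplitPlan:
    """Index sets for a holdout split or a k-fold rotation."""

    scheme: str
    seed: int
    train: np.ndarray | None = None
    validation: np.ndarray | None = None
    test: np.ndarray | None = None
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None  # (train, test) pairs


def match_detections(
    predictions: list[Detection] | np.ndarray,
    truths: list[Detection] | np.ndarray,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy score-ordered one-to-one matching.

    Count conservation holds by construction: ``TP + FN`` equals the number
    of truths and ``TP + FP`` the number of predictions.
    """
    if isinstance(predictions, np.ndarray):
        predictions = [Detection(box=tuple(b)) for b in predictions.reshape(-1, 4)]
    if isinstance(truths, np.ndarray):
        truths = [Detection(box=tuple(b)) for b in truths.reshape(-1, 4)]
    pred_boxes, pred_scores = detections_to_array(predictions)
    truth_boxes, _ = detections_to_array(truths)
    n_pred, n_truth = len(predictions), len(truths)
    if n_pred == 0 or n_truth == 0:
        return MatchResult(tp=0, fp=n_pred, fn=n_truth)
    iou = box_iou_matrix(pred_boxes, truth_boxes)
    order = np.argsort(-pred_scores, kind="stable")
    matched_truth = np.zeros(n_truth, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        candidates = np.where(~matched_truth, iou[pi], -1.0)
        ti = int(candidates.argmax())
        if candidates[ti] >= iou_threshold:
            matched_truth[ti] = True
            pairs.append((int(pi), ti, float(iou[pi, ti])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_truth - tp, pairs=pairs)


def compute_metrics(match: MatchResult) -> dict[str, float]:
    """Precision, recall, F1 and detection accuracy from match counts.

    Zero denominators yield 0 by convention (logged, and flagged in the
    ``degenerate`` field).
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    if degenerate:
        logger.info("degenerate metric case: TP=%d FP=%d FN=%d", tp, fp, fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "degenerate": degenerate,
    }


def make_splits(n_items: int, scheme: str = "holdout", seed: int = 0, k: int = 10) -> SplitPlan:
    """Deterministic split plan.

    ``scheme="holdout"`` shuffles and cuts 60/20/20 (train/validation/test,
    rounding remainders into train); ``scheme="kfold"`` rotates ``k`` folds
    whose sizes differ by at most one.
    """
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    if scheme == "holdout":
        n_val = int(round(0.2 * n_items))
        n_test = int(round(0.2 * n_items))
        test = np.sort(perm[:n_test])
        val = np.sort(perm[n_test : n_test + n_val])
        train = np.sort(perm[n_test + n_val :])
        return SplitPlan(scheme="holdout", seed=seed, train=train, validation=val, test=test)
    if scheme == "kfold":
        if n_items < k:
            raise ValueError(f"need at least k={k} items for k-fold, got {n_items}")
        folds_idx = np.array_split(perm, k)
        folds = []
        for i in range(k):
            test = np.sort(folds_idx[i])
            train = np.sort(np.concatenate([folds_idx[j] for j in range(k) if j != i]))
            folds.append((train, test))
        return SplitPlan(scheme="kfold", seed=seed, folds=folds)
    raise ValueError(f"unknown scheme {scheme!r}")
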