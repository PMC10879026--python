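"""Threshold + morphology cell segmentation and counting.

The chain is: pick a threshold ``T`` (Otsu by default), split the image into
background ``B`` (``I > T``) and foreground ``F`` (``I <= T``, so dark cells
are foreground), erode ``B`` and dilate ``F`` with a structuring element
``S``, and combine::

    R(i,j) = 1  iff  F_dilated(i,j) = 1 and B_eroded(i,j) = 0

Connected components of ``R`` above a minimum area are the detected cells.
Out-of-bounds neighbours are treated as 0 for both erosion and dilation, so
morphological duality holds on interior pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Region",
    "square_selem",
    "select_threshold",
    "threshold_split",
    "erode",
    "dilate",
    "combine",
    "segment_image",
    "count_cells",
    "ThresholdSegmenter",
]


@dataclass
class Region:
    """One connected component of the segmentation result."""

    label: int
    area: int
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open
    centroid: tuple[float, float]  # (x, y)


def square_selem(size: int = 3) -> np.ndarray:
    """Square structuring element of odd side ``size`` (anchor at center)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element side must be a positive odd integer")
    return np.ones((size, size), dtype=bool)


def _selem_offsets(S: np.ndarray | list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Normalize a structuring element to a list of (dp, dq) offsets."""
    if isinstance(S, np.ndarray):
        if S.ndim != 2 or not np.any(S):
            raise ValueError("structuring element must be a non-empty 2-D array")
        cy, cx = S.shape[0] // 2, S.shape[1] // 2
        offsets = [(int(p - cy), int(q - cx)) for p, q in zip(*np.nonzero(S))]
    else:
        offsets = [(int(p), int(q)) for p, q in S]
        if not offsets:
            raise ValueError("structuring element must be non-empty")
    if (0, 0) not in offsets:
        raise ValueError("structuring element must contain the origin")
    return offsets


def select_threshold(image: np.ndarray, method: str | float = "otsu") -> float:
    """Select the segmentation threshold ``T``.

    ``method="otsu"`` maximizes between-class variance over a 256-bin
    histogram; a float selects that fixed value. A constant image has no
    meaningful threshold and raises.
    """
    image = np.asarray(image, dtype=float)
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.unique(image).size < 2:
        raise ValueError("cannot select a threshold on a constant image")
    return float(threshold_otsu(image, nbins=256))


def threshold_split(image: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Split into background ``B`` (``I > T``) and foreground ``F`` (``I <= T``).

    ``B`` and ``F`` partition the grid; a pixel exactly at ``T`` is
    foreground.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    F = (image <= T).astype(np.uint8)
    B = 1 - F
    return B, F


def _shift(mask: np.ndarray, dp: int, dq: int) -> np.ndarray:
    """``out(i,j) = mask(i+dp, j+dq)`` with out-of-bounds values 0."""
    m, n = mask.shape
    out = np.zeros_like(mask)
    y0, y1 = max(0, -dp), min(m, m - dp)
    x0, x1 = max(0, -dq), min(n, n - dq)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = mask[y0 + dp : y1 + dp, x0 + dq : x1 + dq]
    return out


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary")
    return mask.astype(np.uint8)


def erode(mask: np.ndarray, S: np.ndarray | list[tuple[int, int]] | None = None) -> np.ndarray:
    """Morphological erosion: ``out(i,j) = min over (p,q) in S of mask(i+p, j+q)``.

    Out-of-bounds neighbours count as 0, so a full mask loses its border.
    """
    mask = _check_binary(mask)
    out = np.ones_like(mask)
    for dp, dq in _selem_offsets(square_selem() if S is None else S):
        out &= _shift(mask, dp, dq)
    return out


def dilate(mask: np.ndarray, S: np.ndarray | list[tuple[int, int]] | None = None) -> np.ndarray:
    """Morphological dilation: ``out(i,j) = max over (p,q) in S of mask(i+p, j+q)``."""
    mask = _check_binary(mask)
    out = np.zeros_like(mask)
    for dp, dq in _selem_offsets(square_selem() if S is None else S):
        out |= _shift(mask, dp, dq)
    return out


def combine(F_dilated: np.ndarray, B_eroded: np.ndarray) -> np.ndarray:
    """Segmentation result: 1 where the dilated foreground is set and the
    eroded background is not."""
    F_dilated = _check_binary(F_dilated)
    B_eroded = _check_binary(B_eroded)
    if F_dilated.shape != B_eroded.shape:
        raise ValueError("mask shapes differ")
    return ((F_dilated == 1) & (B_eroded == 0)).astype(np.uint8)


def segment_image(
    image: np.ndarray,
    threshold: str | float = "otsu",
    S: np.ndarray | None = None,
    polarity: str = "dark",
) -> np.ndarray:
    """Full threshold -> split -> erode/dilate -> combine chain.

    ``polarity="dark"`` treats low intensities as cells (the default
    convention); ``"bright"`` inverts the image first.
    """
    image = np.asarray(image, dtype=float)
    if polarity == "bright":
        image = 1.0 - image
    elif polarity != "dark":
        raise ValueError("polarity must be 'dark' or 'bright'")
    T = select_threshold(image, threshold)
    B, F = threshold_split(image, T)
    S = square_selem() if S is None else S
    return combine(dilate(F, S), erode(B, S))


def count_cells(R: np.ndarray, min_area: int = 30) -> tuple[int, list[Region]]:
    """Count 8-connected components of a binary mask, dropping small ones.

    Returns the count and a :class:`Region` per surviving component with its
    tight half-open bounding box and centroid.
    """
    R = _check_binary(R)
    labeled = cc_label(R, connectivity=2)
    regions: list[Region] = []
    for rp in regionprops(labeled):
        if rp.area < min_area:
            continue
        y0, x0, y1, x1 = rp.bbox
        regions.append(
            Region(
                label=int(rp.label),
                area=int(rp.area),
                box=(float(x0), float(y0), float(x1), float(y1)),
                centroid=(float(rp.centroid[1]), float(rp.centroid[0])),
            )
        )
    return len(regions), regions


class ThresholdSegmenter(TransformerMixin, BaseEstimator):
    """Threshold/morphology segmenter with the scikit-learn interface.

    ``fit`` selects and stores the threshold on an image; ``transform``
    produces the binary result mask; :meth:`count` runs the full chain and
    returns the component count and regions.

    Parameters
    ----------
    threshold : "otsu" or float
    selem_size : int
        Side of the square structuring element.
    min_area : int
        Components smaller than this many pixels are discarded by
        :meth:`count`.
    polarity : "dark" or "bright"
        Whether cells are darker or brighter than the background.
    """

    def __init__(
        self,
        threshold: str | float = "otsu",
        selem_size: int = 3,
        min_area: int = 30,
        polarity: str = "dark",
    ):
        self.threshold = threshold
        self.selem_size = selem_size
        self.min_area = min_area
        self.polarity = polarity

    def _oriented(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if self.polarity == "bright":
            return 1.0 - image
        if self.polarity != "dark":
            raise ValueError("polarity must be 'dark' or 'bright'")
        return image

    def fit(self, X, y=None):
        self.threshold_ = select_threshold(self._oriented(X), self.threshold)
        return self

    def transform(self, X) -> np.ndarray:
        image = self._oriented(X)
        T = getattr(self, "threshold_", None)
        if T is None or not isinstance(self.threshold, str):
            T = select_threshold(image, self.threshold)
        B, F = threshold_split(image, T)
        S = square_selem(self.selem_size)
        return combine(dilate(F, S), erode(B, S))

    def count(self, X) -> tuple[int, list[Region]]:
        return count_cells(self.fit(X).transform(X), min_area=self.min_area)
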