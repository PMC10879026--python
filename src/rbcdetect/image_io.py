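"""Reading, writing and basic geometry of grayscale microscopy images.

In-memory images are float32/float64 numpy arrays of shape ``(m, n)`` with
intensities normalized to ``[0, 1]``. Coordinates are 0-based; boxes are
half-open (see :mod:`rbcdetect.boxes`).
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .boxes import Detection

__all__ = [
    "DEFAULT_PATCH_SIZE",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "to_gray",
    "normalize",
    "resize",
    "extract_patch",
    "write_boxes_csv",
    "read_boxes_csv",
]

#: Default working size for per-region classifier patches.
DEFAULT_PATCH_SIZE = (24, 24)

_SUPPORTED_EXT = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

# ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


def _check_ext(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ValueError(f"unsupported image format {ext!r}; expected one of {sorted(_SUPPORTED_EXT)}")
    return ext


def to_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an ``(m, n[, 3|4])`` array to single-channel using BT.601 weights."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA
    raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")


def read_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a grayscale float array in ``[0, 1]``.

    Integer images are divided by the dtype maximum; float images (TIFF)
    are taken as already normalized and clipped to ``[0, 1]``.
    """
    _check_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = iio.imread(path)
    gray = to_gray(raw)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        gray = gray / float(np.iinfo(np.asarray(raw).dtype).max)
    return np.clip(gray, 0.0, 1.0).astype(np.float64)


def write_image(path: str, image: np.ndarray) -> None:
    """Write a normalized image: 8-bit for PNG/JPEG, float32 for TIFF."""
    ext = _check_ext(path)
    image = np.asarray(image, dtype=float)
    if ext in (".tif", ".tiff"):
        iio.imwrite(path, image.astype(np.float32))
    else:
        iio.imwrite(path, np.round(np.clip(image, 0.0, 1.0) * 255).astype(np.uint8))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Write an integer instance/label mask as a 16-bit PNG."""
    if os.path.splitext(str(path))[1].lower() != ".png":
        raise ValueError("instance masks are written as 16-bit PNG")
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels out of uint16 range")
    iio.imwrite(path, mask.astype(np.uint16))


def read_mask(path: str) -> np.ndarray:
    """Read an integer label mask written by :func:`write_mask`."""
    return np.asarray(iio.imread(path)).astype(np.int64)


def normalize(image: np.ndarray) -> np.ndarray:
    """Affinely map intensities so min -> 0 and max -> 1.

    A constant image maps to all zeros (the 0/0 case is defined away).
    Raises on NaN/Inf pixels.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def resize(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``size = (height, width)``.

    Identical input/output size returns a copy. Bilinear interpolation does
    not overshoot, so the output range stays within the input range.
    """
    m, n = int(size[0]), int(size[1])
    if m <= 0 or n <= 0:
        raise ValueError(f"target size must be positive, got {size}")
    image = np.asarray(image, dtype=float)
    if image.shape == (m, n):
        return image.copy()
    return _sk_resize(image, (m, n), order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def extract_patch(
    image: np.ndarray,
    box: tuple[float, float, float, float],
    size: tuple[int, int] = DEFAULT_PATCH_SIZE,
) -> np.ndarray:
    """Crop a (half-open) box out of the image and resize it to a square patch.

    The crop is rounded outward to whole pixels and clipped to the image;
    an empty crop raises.
    """
    image = np.asarray(image, dtype=float)
    m, n = image.shape
    x0 = int(np.clip(np.floor(box[0]), 0, n))
    y0 = int(np.clip(np.floor(box[1]), 0, m))
    x1 = int(np.clip(np.ceil(box[2]), 0, n))
    y1 = int(np.clip(np.ceil(box[3]), 0, m))
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"box {box} has empty intersection with image of shape {image.shape}")
    return resize(image[y0:y1, x0:x1], size)


def write_boxes_csv(
    path: str, detections: list[Detection], image_name: str = "", with_scores: bool = False
) -> None:
    """Write boxes as CSV: ``image,x0,y0,x1,y1[,score],label``."""
    rows = []
    for d in detections:
        row = {"image": image_name, "x0": d.box[0], "y0": d.box[1], "x1": d.box[2], "y1": d.box[3]}
        if with_scores:
            row["score"] = d.score
        row["label"] = d.label
        rows.append(row)
    cols = ["image", "x0", "y0", "x1", "y1"] + (["score"] if with_scores else []) + ["label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_boxes_csv(path: str) -> list[Detection]:
    """Read boxes written by :func:`write_boxes_csv`."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            Detection(
                box=(float(r["x0"]), float(r["y0"]), float(r["x1"]), float(r["y1"])),
                score=float(r["score"]) if "score" in df.columns else 1.0,
                label=str(r.get("label", "rbc")),
            )
        )
    return out
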