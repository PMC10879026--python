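"""Training-set augmentation: random affine warps applied consistently to
images and their bounding boxes.

The sampled transform composes, about the image center: horizontal flip
(Bernoulli 1/2 when enabled), zoom ``~ U(1 - z, 1 + z)``, shear, rotation
(degrees), and pixel shifts drawn as fractions of the image width/height.
An intensity rescale factor (default 1/255, the usual 8-bit normalization)
is applied before warping. Boxes are mapped by transforming their four
corners and taking the axis-aligned hull, clipped to the image; boxes that
collapse to zero area are dropped.

Geometry uses continuous coordinates with pixel centers at ``i + 0.5``, so
a horizontal flip maps a box edge ``x`` to ``n - x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp
from sklearn.base import BaseEstimator

from .boxes import Detection

__all__ = ["AugmentConfig", "RandomAugmenter", "sample_transform", "apply_transform", "augment"]

_FILL_MODES = {"nearest": "edge", "constant": "constant", "reflect": "reflect"}


@dataclass
class AugmentConfig:
    """Augmentation ranges (training-set defaults).

    ``rotation_range`` is in degrees, ``shear_range`` in radians,
    ``width_shift``/``height_shift`` are fractions of the image width/height,
    and ``zoom_range`` z draws a scale from ``U(1 - z, 1 + z)``.
    """

    rescale: float = 1.0 / 255.0
    rotation_range: float = 0.2
    width_shift: float = 0.2
    height_shift: float = 0.1
    shear_range: float = 0.1
    zoom_range: float = 0.5
    horizontal_flip: bool = True
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rescale <= 0:
            raise ValueError("rescale must be positive")
        for name in ("rotation_range", "width_shift", "height_shift", "shear_range", "zoom_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fill_mode not in _FILL_MODES:
            raise ValueError(f"fill_mode must be one of {sorted(_FILL_MODES)}")


def _translation(tx: float, ty: float) -> np.ndarray:
    M = np.eye(3)
    M[0, 2] = tx
    M[1, 2] = ty
    return M


def sample_transform(
    config: AugmentConfig,
    rng: np.random.Generator,
    image_shape: tuple[int, int],
) -> AffineTransform:
    """Draw one random affine transform for an ``(m, n)`` image.

    With all ranges zero and flipping disabled this is exactly the
    identity. Angles are uniform in ``±rotation_range`` degrees, shifts
    uniform in ``±range * size`` pixels, shear uniform in ``±shear_range``
    radians, zoom uniform in ``1 ± zoom_range``.
    """
    m, n = image_shape
    angle = np.deg2rad(rng.uniform(-config.rotation_range, config.rotation_range))
    shift_x = rng.uniform(-config.width_shift, config.width_shift) * n
    shift_y = rng.uniform(-config.height_shift, config.height_shift) * m
    shear = rng.uniform(-config.shear_range, config.shear_range)
    zoom = rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range)
    flip = bool(config.horizontal_flip and rng.random() < 0.5)

    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    Sh = np.array([[1.0, np.tan(shear), 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    Z = np.diag([zoom, zoom, 1.0])
    F = np.diag([-1.0, 1.0, 1.0]) if flip else np.eye(3)
    center = _translation(n / 2.0, m / 2.0)
    uncenter = _translation(-n / 2.0, -m / 2.0)
    M = _translation(shift_x, shift_y) @ center @ R @ Sh @ Z @ F @ uncenter
    return AffineTransform(matrix=M)


def _transform_boxes(
    boxes: list[Detection], t: AffineTransform, image_shape: tuple[int, int]
) -> list[Detection]:
    m, n = image_shape
    out: list[Detection] = []
    for det in boxes:
        x0, y0, x1, y1 = det.box
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]], dtype=float)
        warped = t(corners)
        nx0 = float(np.clip(warped[:, 0].min(), 0, n))
        nx1 = float(np.clip(warped[:, 0].max(), 0, n))
        ny0 = float(np.clip(warped[:, 1].min(), 0, m))
        ny1 = float(np.clip(warped[:, 1].max(), 0, m))
        if nx1 - nx0 <= 0 or ny1 - ny0 <= 0:
            continue
        out.append(Detection(box=(nx0, ny0, nx1, ny1), score=det.score, label=det.label))
    return out


def apply_transform(
    image: np.ndarray,
    boxes: list[Detection],
    t: AffineTransform,
    fill_mode: str = "nearest",
) -> tuple[np.ndarray, list[Detection]]:
    """Warp an image and its boxes by a forward affine map.

    The identity transform is a bit-exact no-op. Raises on a singular
    transform.
    """
    image = np.asarray(image, dtype=float)
    M = np.asarray(t.params if hasattr(t, "params") else t, dtype=float)
    if abs(np.linalg.det(M[:2, :2])) < 1e-12:
        raise ValueError("singular affine transform")
    if fill_mode not in _FILL_MODES:
        raise ValueError(f"fill_mode must be one of {sorted(_FILL_MODES)}")
    new_boxes = _transform_boxes(boxes, AffineTransform(matrix=M), image.shape)
    if np.array_equal(M, np.eye(3)):
        return image.copy(), new_boxes
    # skimage's warp works in index coordinates (pixel centers at integers);
    # our matrices use continuous coordinates with centers at i + 0.5.
    shift = _translation(0.5, 0.5)
    M_idx = np.linalg.inv(shift) @ M @ shift
    inv = np.linalg.inv(M_idx)
    warped = warp(
        image,
        AffineTransform(matrix=inv),
        mode=_FILL_MODES[fill_mode],
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    return warped, new_boxes


def augment(
    image: np.ndarray,
    boxes: list[Detection],
    config: AugmentConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[Detection]]:
    """Rescale intensities, then apply one randomly sampled affine warp."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    image = np.asarray(image, dtype=float) * config.rescale
    t = sample_transform(config, rng, image.shape)
    return apply_transform(image, boxes, t, config.fill_mode)


class RandomAugmenter(BaseEstimator):
    """Random affine augmenter with scikit-learn parameter plumbing.

    Each call to :meth:`transform` consumes the next draw from the seeded
    stream, so a fresh instance with the same seed replays the same
    sequence of transforms.
    """

    def __init__(
        self,
        rescale: float = 1.0 / 255.0,
        rotation_range: float = 0.2,
        width_shift: float = 0.2,
        height_shift: float = 0.1,
        shear_range: float = 0.1,
        zoom_range: float = 0.5,
        horizontal_flip: bool = True,
        fill_mode: str = "nearest",
        seed: int = 0,
    ):
        self.rescale = rescale
        self.rotation_range = rotation_range
        self.width_shift = width_shift
        self.height_shift = height_shift
        self.shear_range = shear_range
        self.zoom_range = zoom_range
        self.horizontal_flip = horizontal_flip
        self.fill_mode = fill_mode
        self.seed = seed

    def _config(self) -> AugmentConfig:
        return AugmentConfig(
            rescale=self.rescale,
            rotation_range=self.rotation_range,
            width_shift=self.width_shift,
            height_shift=self.height_shift,
            shear_range=self.shear_range,
            zoom_range=self.zoom_range,
            horizontal_flip=self.horizontal_flip,
            fill_mode=self.fill_mode,
            seed=self.seed,
        )

    def fit(self, X=None, y=None):
        self._config()  # validates
        self.rng_ = np.random.default_rng(self.seed)
        return self

    def transform(self, image: np.ndarray, boxes: list[Detection] | None = None):
        if not hasattr(self, "rng_"):
            self.fit()
        return augment(image, boxes or [], self._config(), self.rng_)
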