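"""Synthetic blood-smear scenes with exact ground truth.

Generates fields of roughly circular/elliptical cells — darker than the
background by default, as in stained bright-field smears — with optional
touching clusters, a gentle background gradient, and additive Gaussian plus
multiplicative speckle noise. Every scene carries its instance mask and the
tight bounding box of each cell, so segmentation and detection stages can be
scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .boxes import Detection

__all__ = ["SceneParams", "GroundTruthScene", "generate_scene", "render_cell", "add_noise"]

#: Minimum clearance (pixels) between non-cluster cells, in addition to the
#: sum of radii; keeps components separable through a 3x3 dilation.
_SEPARATION_MARGIN = 4.0


@dataclass
class SceneParams:
    """Study conditions for one synthetic smear field.

    All intensities are normalized to ``[0, 1]``; cells are darker than the
    background when ``cell_intensity < background_intensity`` (the default).
    """

    image_height: int = 256
    image_width: int = 256
    n_cells: int = 20
    radius_range: tuple[float, float] = (8.0, 12.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.4)
    overlap_fraction: float = 0.0
    cell_intensity: float = 0.35
    background_intensity: float = 0.85
    background_gradient: float = 0.05
    noise_sigma: float = 0.02
    speckle_strength: float = 0.0
    edge_width: float = 1.5
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        e0, e1 = self.eccentricity_range
        if not (0.0 <= e0 <= e1 < 1.0):
            raise ValueError("eccentricity_range must lie in [0, 1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for name in ("cell_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruthScene:
    """A rendered image plus its exact annotations.

    ``instance_mask`` labels each cell with a distinct positive integer
    (0 = background); ``boxes`` holds one unit-score :class:`Detection` per
    cell, each the tight bounding box of its mask component.
    """

    image: np.ndarray
    boxes: list[Detection]
    instance_mask: np.ndarray
    params: SceneParams | None = None
    cells: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.boxes)


def _ellipse_alpha(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    orientation: float,
    edge_width: float,
) -> np.ndarray:
    """Coverage field in [0, 1]: 1 inside, raised-cosine ramp across the rim.

    The ramp spans ``edge_width`` pixels centered on the ellipse boundary,
    so the 0.5-level contour is the ellipse itself.
    """
    m, n = shape
    cx, cy = center
    a, b = radii
    # Bound the affected window to keep rendering O(cell area).
    rmax = max(a, b) + edge_width + 1.0
    y0 = max(0, int(np.floor(cy - rmax)))
    y1 = min(m, int(np.ceil(cy + rmax)) + 1)
    x0 = max(0, int(np.floor(cx - rmax)))
    x1 = min(n, int(np.ceil(cx + rmax)) + 1)
    alpha = np.zeros(shape)
    if y1 <= y0 or x1 <= x0:
        return alpha
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx + 0.5) - cx
    dy = (yy + 0.5) - cy
    if a == b:
        # circles are rotation-invariant; skip the rotation so the rendered
        # support is bit-identical for any orientation
        u, v = dx, dy
    else:
        ct, st = np.cos(orientation), np.sin(orientation)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # Signed pixel distance to the boundary (exact for circles, good enough
    # for the mild eccentricities used here).
    d = (rho - 1.0) * min(a, b)
    e = max(edge_width, 1e-6)
    ramp = 0.5 * (1.0 - np.sin(np.clip(d / e, -1.0, 1.0) * (np.pi / 2)))
    block = np.where(d <= -e, 1.0, np.where(d >= e, 0.0, ramp))
    alpha[y0:y1, x0:x1] = block
    return alpha


def render_cell(
    canvas: np.ndarray,
    center: tuple[float, float],
    radii: tuple[float, float],
    orientation: float = 0.0,
    intensity: float = 0.35,
    edge_width: float = 1.5,
) -> np.ndarray:
    """Composite one elliptical cell onto a canvas.

    Pixels inside the ellipse move toward ``intensity`` with a smooth
    raised-cosine rim; pixels outside the rim band are untouched.

    Parameters
    ----------
    center : (x, y) pixel coordinates; must lie inside the canvas.
    radii : (a, b) semi-axes in pixels, both positive.
    orientation : major-axis angle in radians.
    """
    canvas = np.asarray(canvas, dtype=float)
    m, n = canvas.shape
    if not (0 <= center[0] < n and 0 <= center[1] < m):
        raise ValueError(f"cell center {center} outside canvas of shape {canvas.shape}")
    if radii[0] <= 0 or radii[1] <= 0:
        raise ValueError(f"radii must be positive, got {radii}")
    alpha = _ellipse_alpha(canvas.shape, center, radii, orientation, edge_width)
    return canvas * (1.0 - alpha) + intensity * alpha


def add_noise(
    image: np.ndarray,
    noise_sigma: float,
    speckle_strength: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Additive Gaussian plus multiplicative speckle noise, clipped to [0, 1].

    ``out = clip(I * (1 + speckle * u) + g)`` with ``u, g`` standard normal
    fields (``g`` scaled by ``noise_sigma``). Zero noise returns the input
    unchanged.
    """
    image = np.asarray(image, dtype=float)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if speckle_strength < 0:
        raise ValueError("speckle_strength must be >= 0")
    if noise_sigma == 0 and speckle_strength == 0:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = image.copy()
    if speckle_strength > 0:
        out = out * (1.0 + speckle_strength * rng.standard_normal(image.shape))
    if noise_sigma > 0:
        out = out + noise_sigma * rng.standard_normal(image.shape)
    return np.clip(out, 0.0, 1.0)


def _sample_cell_geometry(rng: np.random.Generator, params: SceneParams) -> tuple[float, float, float]:
    """Draw (a, b, orientation) from the configured radius/eccentricity ranges."""
    r = rng.uniform(*params.radius_range)
    ecc = rng.uniform(*params.eccentricity_range)
    # a >= b with b = a * sqrt(1 - ecc^2); keep the mean radius near r.
    ratio = np.sqrt(1.0 - ecc**2)
    a = r / np.sqrt(ratio)
    b = r * np.sqrt(ratio)
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def generate_scene(params: SceneParams) -> GroundTruthScene:
    """Render one smear field with ground truth.

    Roughly ``overlap_fraction * n_cells`` cells are placed as cluster
    members at center distance below the sum of radii from a host cell;
    the remainder are placed with rejection sampling so they keep a margin
    from every other cell. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    m, n = params.image_height, params.image_width

    # Background with a gentle horizontal gradient.
    canvas = np.full((m, n), params.background_intensity, dtype=float)
    if params.background_gradient > 0 and n > 1:
        slope = params.background_gradient * (np.arange(n) / (n - 1) - 0.5)
        canvas = np.clip(canvas + slope[None, :], 0.0, 1.0)

    # Target number of cells that should end up with a touching neighbour.
    # Each cluster member makes itself and (if previously isolated) its host
    # "involved", so the achieved fraction tracks the target.
    target_involved = int(round(params.overlap_fraction * params.n_cells))
    placements: list[dict] = []
    involved: set[int] = set()
    for k in range(params.n_cells):
        a, b, theta = _sample_cell_geometry(rng, params)
        rmax = max(a, b)
        as_member = len(involved) < target_involved and len(placements) > 0
        placed = False
        for _ in range(params.max_retries):
            if as_member:
                isolated = [i for i in range(len(placements)) if i not in involved]
                pool = isolated if isolated else list(range(len(placements)))
                host_idx = pool[int(rng.integers(len(pool)))]
                host = placements[host_idx]
                host_r = max(host["radii"])
                d = rng.uniform(0.6, 0.95) * (host_r + rmax)
                ang = rng.uniform(0.0, 2 * np.pi)
                cx = host["center"][0] + d * np.cos(ang)
                cy = host["center"][1] + d * np.sin(ang)
                if not (rmax <= cx < n - rmax and rmax <= cy < m - rmax):
                    continue
                involved.add(host_idx)
                involved.add(k)
                placed = True
                break
            cx = rng.uniform(rmax, n - rmax)
            cy = rng.uniform(rmax, m - rmax)
            ok = True
            for p in placements:
                dist = np.hypot(cx - p["center"][0], cy - p["center"][1])
                if dist < rmax + max(p["radii"]) + _SEPARATION_MARGIN:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {k + 1}/{params.n_cells} after "
                f"{params.max_retries} retries; image too small for the requested packing"
            )
        placements.append({"center": (cx, cy), "radii": (a, b), "orientation": theta})

    instance_mask = np.zeros((m, n), dtype=np.int32)
    for label, p in enumerate(placements, start=1):
        alpha = _ellipse_alpha((m, n), p["center"], p["radii"], p["orientation"], params.edge_width)
        canvas = canvas * (1.0 - alpha) + params.cell_intensity * alpha
        instance_mask[alpha >= 0.5] = label

    # Tight boxes from the mask; a cell fully occluded by later neighbours
    # would lose its label, which the placement rules prevent.
    boxes: list[Detection] = []
    kept: list[dict] = []
    relabel = np.zeros(instance_mask.max() + 1, dtype=np.int32)
    next_label = 1
    for label, p in enumerate(placements, start=1):
        ys, xs = np.nonzero(instance_mask == label)
        if ys.size == 0:
            continue
        relabel[label] = next_label
        next_label += 1
        boxes.append(
            Detection(box=(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)))
        )
        kept.append(p)
    instance_mask = relabel[instance_mask]

    image = add_noise(canvas, params.noise_sigma, params.speckle_strength, rng)
    return GroundTruthScene(image=image, boxes=boxes, instance_mask=instance_mask, params=params, cells=kept)


def generate_scenes(params: SceneParams, n_scenes: int, seed: int | None = None) -> list[GroundTruthScene]:
    """Generate ``n_scenes`` independent scenes, reseeding each from ``seed``."""
    base = params.seed if seed is None else seed
    return [generate_scene(replace(params, seed=int(base) + i)) for i in range(n_scenes)]
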