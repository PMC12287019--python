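"""Vertebral-body segmentation: binarization, binary morphology, component
filtering, per-component convex-hull regularization, and top-to-bottom
L1..L5 labeling.

Morphology uses the standard set definitions: dilation keeps every
translation z whose reflected structuring element hits the foreground,
erosion keeps z where the structuring element fits entirely inside the
foreground (out-of-image pixels count as background).  Foreground
connectivity is 8, background (hole) connectivity 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.filters import threshold_otsu

__all__ = [
    "StructuringElement", "VertebraRegion", "SegmentConfig",
    "binarize", "dilate", "erode", "closing", "opening", "fill_holes", "clear_border",
    "filter_components", "convex_hull_regions", "label_vertebrae",
    "segment_pipeline", "trace_contour",
]

LEVEL_NAMES = ("L1", "L2", "L3", "L4", "L5")


@dataclass(frozen=True)
class StructuringElement:
    """Symmetric structuring element B centered on its origin."""

    shape: str = "disk"     # "disk" | "square"
    radius: int = 2         # radius (disk) or half-width (square)

    def footprint(self) -> np.ndarray:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.shape == "disk":
            return morphology.disk(self.radius).astype(bool)
        if self.shape == "square":
            k = 2 * self.radius + 1
            return np.ones((k, k), dtype=bool)
        raise ValueError(f"unknown structuring element shape {self.shape!r}")


@dataclass
class VertebraRegion:
    """A single labeled vertebral body: mask, traced contour and geometry."""

    level: str
    mask: np.ndarray            # bool, full image shape, one 8-connected component
    contour: np.ndarray         # (n, 2) float array of (x, y) vertices, closed implicitly
    centroid: tuple[float, float]   # (g_x, g_y), x = column, y = row
    area: int


@dataclass
class SegmentConfig:
    """Parameters of the full segmentation chain."""

    threshold: str = "otsu"          # "otsu" or "fixed"
    fixed_threshold: int = 128
    se: StructuringElement = field(default_factory=StructuringElement)
    closing: bool = True             # dilate then erode before hole filling
    min_area_fraction: float = 0.05
    centroid_band_fraction: float = 0.15
    expected_n: int = 5


def binarize(img: np.ndarray, method: str = "otsu", threshold: int | None = None) -> np.ndarray:
    """Foreground = pixels strictly above the threshold."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization needs a threshold")
        t = threshold
    elif method == "otsu":
        if img.min() == img.max():
            raise ValueError("degenerate histogram: constant image has no Otsu threshold")
        t = threshold_otsu(img)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return img > t


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Minkowski dilation: z kept iff the reflected SE translated to z hits A."""
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool),
                                   structure=se.footprint())


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion with the fit condition (B)_z subset of A; pixels beyond the
    image border count as background, so a full-frame mask loses a border band."""
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool),
                                  structure=se.footprint(), border_value=0)


def closing(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion with infinite-plane semantics: the mask
    is padded by the SE radius so the intermediate dilation is not clipped at
    the frame, making the operation extensive and idempotent."""
    r = se.radius
    padded = np.pad(np.asarray(mask, dtype=bool), r)
    out = erode(dilate(padded, se), se)
    return out[r:-r, r:-r] if r else out


def opening(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation (anti-extensive, idempotent)."""
    return dilate(erode(mask, se), se)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set 4-connected background components not reaching the border to foreground."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool), structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))


def clear_border(mask: np.ndarray) -> np.ndarray:
    """Remove 8-connected components that touch any image border."""
    return segmentation.clear_border(measure.label(np.asarray(mask, dtype=bool), connectivity=2)) > 0


def filter_components(mask: np.ndarray, min_area_fraction: float = 0.05,
                      centroid_band_fraction: float = 0.15) -> np.ndarray:
    """Drop small islands, then keep components whose centroid x lies inside a
    band around the median centroid x.

    Islands with area below ``min_area_fraction`` of the largest component are
    removed first; the band test then keeps components with
    ``|centroid_x - median(centroid_x)| <= centroid_band_fraction * width``.
    """
    if not 0 < min_area_fraction <= 1 or not 0 < centroid_band_fraction <= 1:
        raise ValueError("fractions must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if not props:
        raise ValueError("no components in mask")
    areas = np.array([p.area for p in props])
    keep = areas >= min_area_fraction * areas.max()
    survivors = [p for p, k in zip(props, keep) if k]
    cx = np.array([p.centroid[1] for p in survivors])
    band = centroid_band_fraction * mask.shape[1]
    in_band = np.abs(cx - np.median(cx)) <= band
    out = np.zeros_like(mask)
    for p, ok in zip(survivors, in_band):
        if ok:
            out[lab == p.label] = True
    return out


def convex_hull_regions(mask: np.ndarray) -> np.ndarray:
    """Replace each 8-connected component by the filled convex hull of its
    pixel centers.

    Degenerate components (fewer than 3 pixels, or collinear) are their own
    hull: an 8-connected collinear run already contains every pixel center on
    its segment.
    """
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask)
    for p in measure.regionprops(lab):
        r0, c0, r1, c1 = p.bbox
        hull = p.image
        if p.image.sum() >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # Qhull rejects collinear input
                hull = morphology.convex_hull_image(p.image, offset_coordinates=False)
            hull = hull | p.image
        out[r0:r1, c0:c1] |= hull
    return out


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single-component mask as a closed polygon.

    Returns (n, 2) vertices in (x, y) order, clockwise in image coordinates
    (y down), starting at the topmost-then-leftmost contour point.  Vertices
    are sub-pixel (the 0.5 iso-level of the indicator), which gives stable
    perimeter and curvature estimates on rasterized shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask has no contour")
    rc = max(contours, key=len)   # outer boundary is the longest
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    rc = rc - 1.0                 # undo padding
    xy = rc[:, ::-1].copy()       # (row, col) -> (x, y)
    # signed area > 0 means counterclockwise in a y-down frame == clockwise visually;
    # enforce clockwise in image coordinates (negative shoelace with y down)
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 > 0:
        xy = xy[::-1]
    start = np.lexsort((xy[:, 0], xy[:, 1]))[0]   # topmost, then leftmost
    return np.roll(xy, -start, axis=0)


def label_vertebrae(mask: np.ndarray, expected_n: int = 5) -> tuple[list[VertebraRegion], bool]:
    """Sort components by centroid row and label L1..L5 from the top down.

    Returns the regions and a warning flag set when the number of components
    differs from ``expected_n`` (extra components beyond ``expected_n`` are
    dropped from the bottom).
    """
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if not props:
        raise ValueError("no components in mask")
    props.sort(key=lambda p: p.centroid[0])
    warning = len(props) != expected_n
    regions: list[VertebraRegion] = []
    for i, p in enumerate(props[:expected_n]):
        level = LEVEL_NAMES[i] if i < len(LEVEL_NAMES) else f"L{i + 1}"
        m = lab == p.label
        regions.append(VertebraRegion(
            level=level,
            mask=m,
            contour=trace_contour(m),
            centroid=(p.centroid[1], p.centroid[0]),
            area=int(p.area),
        ))
    return regions, warning


def segment_pipeline(img: np.ndarray, config: SegmentConfig | None = None,
                     log: list | None = None) -> tuple[list[VertebraRegion], bool]:
    """Full chain: binarize -> closing -> fill holes -> clear border ->
    component filtering -> convex-hull regularization -> L1..L5 labeling."""
    config = config or SegmentConfig()

    def _log(stage: str, m: np.ndarray) -> None:
        if log is not None:
            log.append({"stage": stage, "n_components": int(measure.label(m, connectivity=2).max())})

    mask = binarize(img, method=config.threshold, threshold=config.fixed_threshold)
    _log("binarize", mask)
    if config.closing:
        mask = closing(mask, config.se)
        _log("closing", mask)
    mask = fill_holes(mask)
    _log("fill_holes", mask)
    mask = clear_border(mask)
    _log("clear_border", mask)
    mask = filter_components(mask, config.min_area_fraction, config.centroid_band_fraction)
    _log("filter_components", mask)
    mask = convex_hull_regions(mask)
    _log("convex_hull", mask)
    return label_vertebrae(mask, expected_n=config.expected_n)
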