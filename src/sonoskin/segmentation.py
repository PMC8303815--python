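"""Lesion segmentation: fully-automated and semi-automated paths.

The fully-automated (FA) path is seed-and-grow: robust intensity
normalization, skin-layer extraction by multilevel Otsu thresholding with
geometric priors, detection of the largest hypoechoic blob in the dermis as
the seed, then region-based active-contour (morphological Chan-Vese)
growing.  The two semi-automated (SA) paths replace the seed with a human
input: either the rasterized freehand outline itself, or the largest-area
axis-aligned rectangle (LAR) inscribed in that outline, both followed by the
same growing step.

Agreement between segmentations is measured with the Dice coefficient; the
success rate of the FA path against a reference segmentation is the fraction
of lesions whose Dice exceeds 0.10 (strictly), a deliberately permissive bar
that asks only that the automatic mask found the lesion at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.segmentation import morphological_chan_vese

from .errors import (GrowthFailureError, LayerDetectionError, MaskError,
                     NoLesionFoundError, NormalizationError, PolygonError)

MIN_LESION_AREA = 10
_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class SkinLayers:
    """Per-column band boundary rows.

    Above-skin band: rows ``[0, epidermis_top)``; epidermis:
    ``[epidermis_top, dermis_top)``; dermis: ``[dermis_top, dermis_bottom)``.
    """

    epidermis_top: np.ndarray
    dermis_top: np.ndarray
    dermis_bottom: np.ndarray

    def __post_init__(self):
        e, d, b = self.epidermis_top, self.dermis_top, self.dermis_bottom
        if not (len(e) == len(d) == len(b)):
            raise LayerDetectionError("layer boundary arrays differ in length")
        if np.any(e < 0) or np.any(d < e) or np.any(b <= d):
            raise LayerDetectionError("layer bands must be ordered with a "
                                      "non-empty dermis in every column")

    def dermis_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows = np.arange(shape[0])[:, None]
        return (rows >= self.dermis_top[None, :]) & (rows < self.dermis_bottom[None, :])


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check the lesion-mask invariants; returns the mask unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < MIN_LESION_AREA:
        raise MaskError(f"lesion mask below the minimum area of {MIN_LESION_AREA} px")
    _, n = ndimage.label(mask, structure=_CONN4)
    if n != 1:
        raise MaskError(f"lesion mask must be a single 4-connected component, got {n}")
    return mask


def preprocess(image: np.ndarray) -> np.ndarray:
    """Robust intensity normalization to make images from different
    machines comparable.

    Rescales to [0, 1] between the 1st and 99th intensity percentiles
    (clipping outliers) and applies a 3x3 median filter to tame impulsive
    noise.  Scale- and offset-invariant by construction.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 64:
        raise NormalizationError("expected a 2-D image of at least 64x64 pixels")
    if not np.all(np.isfinite(image)):
        raise NormalizationError("image contains non-finite values")
    lo, hi = np.percentile(image, [1, 99])
    if hi <= lo:
        raise NormalizationError("constant (or near-constant) image cannot be normalized")
    out = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return ndimage.median_filter(out, size=3)


def extract_layers(image: np.ndarray, *, max_dermis_depth: int | None = None,
                   smooth_cols: int = 15) -> SkinLayers:
    """Extract the above-skin / epidermis / dermis bands.

    Three-class multilevel Otsu thresholding splits the image into dark /
    mid / bright intensities; the geometric priors are that the above-skin
    band is the dark region at the top of each column, the epidermis is the
    first bright (entry-echo) band below it, and the dermis extends from the
    epidermis bottom to ``max_dermis_depth`` rows further (image bottom by
    default).  Per-column boundaries are median-filtered across columns.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    try:
        t_low, t_high = threshold_multiotsu(image, classes=3)
    except ValueError as exc:  # fewer than 3 distinct gray levels
        raise LayerDetectionError("multilevel thresholding failed: "
                                  f"{exc}") from exc
    bright = image >= t_high
    # entry echo: first bright run in each column, required in most columns
    any_bright = bright.any(axis=0)
    if any_bright.mean() < 0.5:
        raise LayerDetectionError("no entry-echo band found")
    first_bright = np.where(any_bright, np.argmax(bright, axis=0), -1)
    fill = int(np.median(first_bright[any_bright]))
    first_bright = np.where(any_bright, first_bright, fill)

    # epidermis bottom: end of the bright run that starts at the entry echo
    dermis_top = np.empty(w, dtype=int)
    for c in range(w):
        r = first_bright[c]
        col = bright[:, c]
        while r < h and col[r]:
            r += 1
        dermis_top[c] = r
    epidermis_top = ndimage.median_filter(first_bright, size=smooth_cols, mode="nearest")
    dermis_top = ndimage.median_filter(dermis_top, size=smooth_cols, mode="nearest")
    dermis_top = np.maximum(dermis_top, epidermis_top + 1)

    if max_dermis_depth is None:
        dermis_bottom = np.full(w, h, dtype=int)
    else:
        dermis_bottom = np.minimum(dermis_top + max_dermis_depth, h)
    if np.any(dermis_bottom <= dermis_top):
        raise LayerDetectionError("empty dermis band in some columns")
    return SkinLayers(epidermis_top=epidermis_top, dermis_top=dermis_top,
                      dermis_bottom=dermis_bottom)


def detect_lesion_seed(image: np.ndarray, layers: SkinLayers, *,
                       k: float = 1.0, opening_radius: int = 2) -> np.ndarray:
    """Detect the lesion seed as the largest hypoechoic blob in the dermis.

    The hypoechoic threshold adapts to the dermis: pixels below
    ``mean(dermis) - k * std(dermis)`` are candidates.  Morphological
    opening (disk of ``opening_radius``) removes speckle-scale clutter;
    among the remaining 4-connected blobs the largest wins, ties broken by
    the shallower centroid.
    """
    image = np.asarray(image, dtype=float)
    dermis = layers.dermis_mask(image.shape)
    vals = image[dermis]
    thresh = vals.mean() - k * vals.std()
    candidates = dermis & (image < thresh)
    selem = _disk(opening_radius)
    candidates = ndimage.binary_opening(candidates, structure=selem)
    lab, n = ndimage.label(candidates, structure=_CONN4)
    if n == 0:
        raise NoLesionFoundError("no hypoechoic candidate blob in the dermis")
    sizes = ndimage.sum(candidates, lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)
    best = order[-1]
    ties = np.nonzero(sizes == sizes[best])[0]
    if len(ties) > 1:
        centroids = ndimage.center_of_mass(candidates, lab, index=ties + 1)
        best = ties[int(np.argmin([c[0] for c in centroids]))]
    seed = lab == best + 1
    if seed.sum() < MIN_LESION_AREA:
        raise NoLesionFoundError(
            f"largest candidate blob is below {MIN_LESION_AREA} px")
    return validate_mask(seed)


def grow_acm(image: np.ndarray, seed: np.ndarray, *, iterations: int = 200,
             smoothing: int = 1, lambda1: float = 1.0, lambda2: float = 1.0,
             within: np.ndarray | None = None) -> np.ndarray:
    """Grow the final lesion mask from a seed with a region-based active
    contour (morphological Chan-Vese).

    ``within``, if given, restricts the evolved region to a mask (the FA
    path passes the dermis band so the contour cannot leak into the
    epidermis or the coupling layer).  With a zero iteration budget the
    largest connected component of the seed is returned unchanged.
    Deterministic for fixed parameters.
    """
    image = np.asarray(image, dtype=float)
    seed = np.asarray(seed, dtype=bool)
    if seed.shape != image.shape:
        raise MaskError("seed and image shapes differ")
    if seed.sum() < MIN_LESION_AREA:
        raise MaskError("seed below minimum lesion area")
    if iterations > 0:
        region = morphological_chan_vese(
            image, num_iter=iterations, init_level_set=seed,
            smoothing=smoothing, lambda1=lambda1, lambda2=lambda2).astype(bool)
    else:
        region = seed
    if within is not None:
        region = region & np.asarray(within, dtype=bool)
    lab, n = ndimage.label(region, structure=_CONN4)
    if n == 0:
        raise GrowthFailureError("active contour collapsed to an empty region")
    # keep the component overlapping the seed most; fall back to largest
    overlaps = ndimage.sum(seed, lab, index=np.arange(1, n + 1))
    if overlaps.max() > 0:
        best = int(np.argmax(overlaps))
    else:
        sizes = ndimage.sum(region, lab, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes))
    out = ndimage.binary_fill_holes(lab == best + 1)
    if out.sum() < MIN_LESION_AREA:
        raise GrowthFailureError("active contour collapsed below the minimum area")
    return validate_mask(out)


def segment_fa(image: np.ndarray, *, k: float = 1.0, iterations: int = 200,
               smoothing: int = 1) -> np.ndarray:
    """Fully-automated pipeline: preprocess, extract layers, seed, grow."""
    pre = preprocess(image)
    layers = extract_layers(pre)
    seed = detect_lesion_seed(pre, layers, k=k)
    dermis = layers.dermis_mask(pre.shape)
    return grow_acm(pre, seed, iterations=iterations, smoothing=smoothing,
                    within=dermis)


def segment_sa(image: np.ndarray, polygon: np.ndarray, *, mode: str = "freehand",
               iterations: int = 200, smoothing: int = 1) -> np.ndarray:
    """Semi-automated pipeline from a freehand outline.

    ``mode='freehand'`` grows from the rasterized outline itself;
    ``mode='lar'`` grows from the largest axis-aligned rectangle inscribed
    in the outline (the quick-to-draw surrogate seed).
    """
    pre = preprocess(image)
    if mode == "freehand":
        seed = freehand_to_mask(polygon, pre.shape)
    elif mode == "lar":
        seed = largest_area_rectangle(polygon, pre.shape)
    else:
        raise ValueError(f"unknown SA mode {mode!r}")
    return grow_acm(pre, seed, iterations=iterations, smoothing=smoothing)


def freehand_to_mask(polygon: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed freehand polygon to a filled mask.

    A pixel belongs to the mask when its center lies strictly inside the
    polygon or exactly on its boundary.  Vertices are (row, col), 0-based;
    parts of the polygon outside the image are clipped without error.
    """
    poly = _as_polygon(polygon)
    h, w = image_shape
    minr, minc, maxr, maxc = _clipped_bbox(poly, h, w)
    rr, cc = np.mgrid[minr:maxr + 1, minc:maxc + 1]
    pts = shapely.points(cc.ravel(), rr.ravel())  # shapely (x, y) = (col, row)
    inside = shapely.intersects(poly, pts).reshape(rr.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[minr:maxr + 1, minc:maxc + 1] = inside
    if not mask.any():
        raise PolygonError("polygon rasterizes to an empty mask")
    return mask


def largest_area_rectangle(polygon: np.ndarray,
                           image_shape: tuple[int, int]) -> np.ndarray:
    """Largest axis-aligned rectangle inscribed in the rasterized polygon.

    Exact on the pixel grid, via the classic row-by-row histogram/stack
    method for the maximal rectangle in a binary matrix.  Ties are broken
    by minimal top row, then minimal left column.  Returns the rectangle as
    a filled mask.
    """
    mask = freehand_to_mask(polygon, image_shape)
    top, left, height, width = _max_rectangle(mask)
    out = np.zeros_like(mask)
    out[top:top + height, left:left + width] = True
    return out


def _max_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(top, left, height, width) of the maximal all-True rectangle."""
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best = (0, 0, 0, 0)  # area implicit via h*w; track separately
    best_area = 0
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        # stack of (start_col, height) with increasing heights
        stack: list[tuple[int, int]] = []
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            start = c
            while stack and stack[-1][1] >= cur:
                s, hh = stack.pop()
                area = hh * (c - s)
                top = r - hh + 1
                cand = (top, s, hh, c - s)
                if area > best_area or (area == best_area and
                                        (cand[0], cand[1]) < (best[0], best[1])):
                    best, best_area = cand, area
                start = s
            if cur > 0 and (not stack or stack[-1][1] < cur):
                stack.append((start, cur))
    return best


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise MaskError("masks must share a shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise MaskError("Dice is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def segmentation_success_rate(fa_masks, ref_masks, threshold: float = 0.10) -> float:
    """Fraction of mask pairs whose Dice strictly exceeds ``threshold``."""
    fa_masks, ref_masks = list(fa_masks), list(ref_masks)
    if len(fa_masks) != len(ref_masks):
        raise MaskError("mask lists must be paired")
    if not fa_masks:
        raise MaskError("success rate of an empty list is undefined")
    hits = sum(dice(a, b) > threshold for a, b in zip(fa_masks, ref_masks))
    return hits / len(fa_masks)


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (rr**2 + cc**2) <= radius**2


def _as_polygon(polygon: np.ndarray) -> shapely.Polygon:
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(np.unique(verts, axis=0)) < 3:
        raise PolygonError("polygon needs at least 3 distinct (row, col) vertices")
    poly = shapely.Polygon(verts[:, ::-1])  # to (x, y) = (col, row)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        raise PolygonError("degenerate polygon")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _clipped_bbox(poly: shapely.Polygon, h: int, w: int) -> tuple[int, int, int, int]:
    minx, miny, maxx, maxy = poly.bounds
    minr = max(int(np.floor(miny)), 0)
    maxr = min(int(np.ceil(maxy)), h - 1)
    minc = max(int(np.floor(minx)), 0)
    maxc = min(int(np.ceil(maxx)), w - 1)
    if minr > maxr or minc > maxc:
        raise PolygonError("polygon lies outside the image")
    return minr, minc, maxr, maxc
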