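"""Analysis regions and the 62-element lesion feature vector.

Three regions are derived from an image and its lesion mask:

* ``L``  — the lesion: all pixels inside the mask;
* ``D``  — the dermis directly under the lesion (for posterior-shadow and
  attenuation features);
* ``LB`` — the boundary lane: pixels within a fixed Euclidean distance of
  the lesion contour, straddling it symmetrically.

From these, 62 features are computed, indexed 1-62:

====== ==========================================================
1-3    attenuation (slope, shadow contrast, slope heterogeneity)
4-5    radial lesion-contrast heterogeneity and mean
6-12   boundary-lane statistics and contrasts
13-15  skewness, kurtosis, histogram entropy of the lesion
16-20  shape (curvature std, circularity, axis ratio, P/A, P/Ma)
21-28  GLCM descriptors, lesion region, horizontal offset
29-41  GLCM descriptors, lesion region, vertical offset
42-49  GLCM descriptors, dermis-under region, horizontal offset
50-62  GLCM descriptors, dermis-under region, vertical offset
====== ==========================================================

Energy, entropy, the two homogeneities and information measure of
correlation II are computed for the vertical direction only, which is why
the vertical blocks hold 13 descriptors and the horizontal blocks 8.  The
index-to-name mapping is frozen in ``feature_map.json`` shipped with the
package.

Gray-level co-occurrence matrices are accumulated over pixel pairs that both
lie inside the (arbitrarily shaped) region, at offset distance 1, with
intensities quantized to ``levels`` gray levels over the region's own
min-max range; counts are symmetrized and normalized to probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import find_contours, regionprops

from .errors import FeatureError, RegionError
from .segmentation import SkinLayers, validate_mask

GLCM_LEVELS = 16
#: Descriptor order inside a vertical GLCM block (all 13).
GLCM_DESCRIPTORS_V = (
    "contrast", "correlation1", "correlation2", "dissimilarity", "energy",
    "entropy", "homogeneity1", "homogeneity2", "max_probability",
    "difference_variance", "difference_entropy", "infocorr1", "infocorr2")
#: Descriptor order inside a horizontal GLCM block (the 8 computed in both
#: directions).
GLCM_DESCRIPTORS_H = (
    "contrast", "correlation1", "correlation2", "dissimilarity",
    "max_probability", "difference_variance", "difference_entropy", "infocorr1")


def _load_feature_names() -> tuple[str, ...]:
    with resources.files(__package__).joinpath("feature_map.json").open() as fh:
        mapping = json.load(fh)
    names = [None] * len(mapping)
    for idx, name in mapping.items():
        names[int(idx) - 1] = name
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _load_feature_names()
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class RegionTriplet:
    """The three analysis regions plus the geometry the radial and
    attenuation features need."""

    lesion: np.ndarray          # bool mask L
    dermis_under: np.ndarray    # bool mask D
    boundary_lane: np.ndarray   # bool mask LB
    dermis_band: np.ndarray     # bool mask of the full dermis band
    centroid: tuple[float, float]
    ray_angles: np.ndarray      # radians
    ray_radii: np.ndarray       # boundary radius along each ray, px

    def __post_init__(self):
        if not (self.lesion.any() and self.dermis_under.any()
                and self.boundary_lane.any()):
            raise RegionError("all three regions must be non-empty")
        if (self.lesion & self.dermis_under).any():
            raise RegionError("lesion and dermis-under regions overlap")


def derive_regions(image: np.ndarray, mask: np.ndarray, layers: SkinLayers,
                   lane_width: int = 5, dermis_depth: int | None = None,
                   n_rays: int = 72, clip_to_dermis: bool = True) -> RegionTriplet:
    """Derive the lesion / dermis-under / boundary-lane regions.

    ``lane_width`` is the Euclidean distance (pixels) from the lesion
    contour within which a pixel belongs to the boundary lane, on both
    sides of the contour.  ``dermis_depth`` caps how far below the lesion
    the dermis-under region extends; by default it equals the lesion's own
    height.  Boundary-lane pixels are excluded from the dermis-under
    region so the three regions probe disjoint tissue.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if lane_width < 1:
        raise RegionError("lane width must be at least 1 px")
    dermis = layers.dermis_mask(mask.shape)
    if clip_to_dermis and (mask & ~dermis).any():
        clipped = mask & dermis
        lab, n = ndimage.label(clipped)
        if n == 0:
            raise RegionError("lesion mask lies outside the dermis band")
        sizes = ndimage.sum(clipped, lab, index=np.arange(1, n + 1))
        mask = lab == 1 + int(np.argmax(sizes))
    mask = validate_mask(mask)

    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    lane = (mask & (d_in <= lane_width)) | (~mask & (d_out <= lane_width))

    rows_with = np.nonzero(mask.any(axis=1))[0]
    height = int(rows_with[-1] - rows_with[0] + 1)
    depth = height if dermis_depth is None else int(dermis_depth)
    dermis_under = np.zeros_like(mask)
    h = mask.shape[0]
    for c in np.nonzero(mask.any(axis=0))[0]:
        bottom = int(np.nonzero(mask[:, c])[0][-1])
        stop = min(int(layers.dermis_bottom[c]), bottom + 1 + depth, h)
        dermis_under[bottom + 1: stop, c] = True
    dermis_under &= dermis
    dermis_under &= ~lane
    if not dermis_under.any():
        raise RegionError("dermis-under region is empty "
                          "(lesion reaches the bottom of the dermis band)")

    centroid = ndimage.center_of_mass(mask)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    radii = _ray_radii(mask, centroid, angles)
    return RegionTriplet(lesion=mask, dermis_under=dermis_under,
                         boundary_lane=lane, dermis_band=dermis,
                         centroid=(float(centroid[0]), float(centroid[1])),
                         ray_angles=angles, ray_radii=radii)


def _ray_radii(mask: np.ndarray, centroid, angles: np.ndarray,
               step: float = 0.5) -> np.ndarray:
    """Boundary radius along each ray from the centroid (last in-mask step)."""
    h, w = mask.shape
    max_r = float(np.hypot(h, w))
    radii = np.empty(len(angles))
    for i, th in enumerate(angles):
        dr, dc = np.sin(th), np.cos(th)
        r, last_inside = 0.0, 0.0
        while r <= max_r:
            rr = int(round(centroid[0] + r * dr))
            cc = int(round(centroid[1] + r * dc))
            if not (0 <= rr < h and 0 <= cc < w):
                break
            if mask[rr, cc]:
                last_inside = r
            elif r - last_inside > 3 * step:
                break  # well outside; stop scanning
            r += step
        radii[i] = last_inside
    return radii


# ---------------------------------------------------------------------------
# first-order features


def attenuation_features(image: np.ndarray, regions: RegionTriplet) -> np.ndarray:
    """Attenuation features (indices 1-3).

    * idx 1, attenuation: least-squares slope of mean lesion intensity per
      row against depth (intensity units per pixel of depth).
    * idx 2, contrast of attenuation: relative intensity deficit of the
      dermis under the lesion versus the laterally adjacent dermis at the
      same depths — the posterior-shadow strength.
    * idx 3, heterogeneity of attenuation: std over columns of the
      per-column intensity-depth slope inside the lesion.
    """
    image = np.asarray(image, dtype=float)
    L = regions.lesion
    rows = np.nonzero(L.any(axis=1))[0]
    if len(rows) < 3:
        raise FeatureError("attenuation undefined for a lesion under 3 rows tall")
    row_means = np.array([image[r, L[r]].mean() for r in rows])
    slope = np.polyfit(rows.astype(float), row_means, 1)[0]

    col_slopes = []
    for c in np.nonzero(L.any(axis=0))[0]:
        rr = np.nonzero(L[:, c])[0]
        if len(rr) >= 3:
            col_slopes.append(np.polyfit(rr.astype(float), image[rr, c], 1)[0])
    heterogeneity = float(np.std(col_slopes, ddof=1)) if len(col_slopes) >= 2 else np.nan

    shadow_contrast = _shadow_contrast(image, regions)
    return np.array([slope, shadow_contrast, heterogeneity])


def _shadow_contrast(image: np.ndarray, regions: RegionTriplet) -> float:
    """Relative darkening of D versus flanking dermis at the same depths."""
    D = regions.dermis_under
    rows = np.nonzero(D.any(axis=1))[0]
    cols = np.nonzero(D.any(axis=0))[0]
    flank = max(5, (cols[-1] - cols[0] + 1) // 2)
    adjacent = np.zeros_like(D)
    left = slice(max(cols[0] - flank, 0), cols[0])
    right = slice(cols[-1] + 1, min(cols[-1] + 1 + flank, D.shape[1]))
    adjacent[rows[0]: rows[-1] + 1, left] = True
    adjacent[rows[0]: rows[-1] + 1, right] = True
    adjacent &= regions.dermis_band
    adjacent &= ~(regions.lesion | regions.boundary_lane | D)
    if not adjacent.any():
        return np.nan
    avg_adj = image[adjacent].mean()
    if avg_adj == 0:
        return np.nan
    return float((avg_adj - image[D].mean()) / avg_adj)


def lesion_contrast_features(image: np.ndarray, regions: RegionTriplet,
                             segment_len: int = 5) -> np.ndarray:
    """Radial boundary-contrast features (indices 4-5).

    Along each ray from the lesion centroid, the mean intensity of the
    ``segment_len`` pixel samples just outside the contour is compared with
    the mean of the samples just inside it:
    ``contrast = (avg_out - avg_in) / (avg_out + avg_in)``.
    idx 4 is the std of the per-ray contrasts (heterogeneity), idx 5 their
    mean.  Rays that leave the image before completing the outer segment
    are skipped; fewer than 8 surviving rays is an error.
    """
    image = np.asarray(image, dtype=float)
    mask = regions.lesion
    h, w = mask.shape
    step = 0.5
    contrasts = []
    for th, radius in zip(regions.ray_angles, regions.ray_radii):
        dr, dc = np.sin(th), np.cos(th)
        inner, outer = [], []
        # walk outward collecting the last `segment_len` in-mask samples and
        # the first `segment_len` out-of-mask samples (nearest-pixel values)
        r = 0.0
        ok = True
        while len(outer) < segment_len:
            rr = int(round(regions.centroid[0] + r * dr))
            cc = int(round(regions.centroid[1] + r * dc))
            if not (0 <= rr < h and 0 <= cc < w):
                ok = len(outer) >= segment_len
                break
            if mask[rr, cc]:
                inner.append(image[rr, cc])
            elif r > radius:
                outer.append(image[rr, cc])
            r += step
        if not ok or len(inner) < segment_len or len(outer) < segment_len:
            continue
        avg_in = float(np.mean(inner[-segment_len:]))
        avg_out = float(np.mean(outer[:segment_len]))
        if avg_in + avg_out == 0:
            continue
        contrasts.append((avg_out - avg_in) / (avg_out + avg_in))
    if len(contrasts) < 8:
        raise FeatureError("fewer than 8 usable radial contrast lines")
    contrasts = np.asarray(contrasts)
    return np.array([float(np.std(contrasts, ddof=1)), float(np.mean(contrasts))])


def boundary_features(image: np.ndarray, regions: RegionTriplet) -> np.ndarray:
    """Boundary-lane features (indices 6-12), evaluated exactly as printed:

    6: avg(LB); 7: std(LB); 8: avg(LB)/avg(L); 9: std(LB)/std(L);
    10: [avg(LB)-avg(L)]/avg(LB); 11: [std(D)-std(L)]/std(D);
    12: [std(LB)-std(L)]/std(LB).

    Zero denominators yield NaN (imputed later under the NaN policy).
    """
    image = np.asarray(image, dtype=float)
    lb = image[regions.boundary_lane]
    le = image[regions.lesion]
    de = image[regions.dermis_under]
    avg_lb, std_lb = lb.mean(), lb.std(ddof=1)
    avg_l, std_l = le.mean(), le.std(ddof=1)
    std_d = de.std(ddof=1)
    return np.array([
        avg_lb,
        std_lb,
        _safe_div(avg_lb, avg_l),
        _safe_div(std_lb, std_l),
        _safe_div(avg_lb - avg_l, avg_lb),
        _safe_div(std_d - std_l, std_d),
        _safe_div(std_lb - std_l, std_lb),
    ])


def statistical_features(image: np.ndarray, regions: RegionTriplet,
                         bins: int = 64) -> np.ndarray:
    """Lesion intensity distribution features (indices 13-15): sample
    skewness, raw (non-excess) kurtosis, and Shannon entropy in bits of the
    ``bins``-bin histogram over the lesion's intensity range."""
    vals = np.asarray(image, dtype=float)[regions.lesion]
    if vals.size < 10:
        raise FeatureError("too few lesion pixels for distribution statistics")
    if vals.std() == 0:
        skew = kurt = np.nan
        entropy = 0.0
    else:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
        counts, _ = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
        p = counts[counts > 0] / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
    return np.array([skew, kurt, entropy])


def shape_features(mask: np.ndarray, contour_sigma: float = 6.0,
                   n_samples: int = 400) -> np.ndarray:
    """Shape features of the lesion mask (indices 16-20).

    The contour is arc-length resampled and Gaussian-smoothed (periodic);
    curvature comes from finite differences of the tangent angle.  With
    P = smoothed contour length, A = pixel area, Ma/ma = major/minor axis
    lengths of the second-moment ellipse:

    16: std(curvature); 17: circularity 4*pi*A/P^2; 18: Ma/ma; 19: P/A;
    20: P/Ma.
    """
    mask = np.asarray(mask, dtype=bool)
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise FeatureError("mask has no contour")
    contour = max(contours, key=len)
    if len(contour) < 8:
        raise FeatureError("lesion contour shorter than 8 points")
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]

    # uniform arc-length resampling of the closed contour
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n_samples, endpoint=False)
    ri = np.interp(si, s, closed[:, 0])
    ci = np.interp(si, s, closed[:, 1])
    ri = ndimage.gaussian_filter1d(ri, sigma=contour_sigma, mode="wrap")
    ci = ndimage.gaussian_filter1d(ci, sigma=contour_sigma, mode="wrap")

    dr = np.diff(np.concatenate([ri, ri[:1]]))
    dc = np.diff(np.concatenate([ci, ci[:1]]))
    ds = np.hypot(dr, dc)
    perimeter = float(ds.sum())
    theta = np.arctan2(dr, dc)
    # turning angle between consecutive segments, wrapped to (-pi, pi]
    dtheta = np.diff(np.concatenate([theta, theta[:1]]))
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    curvature = dtheta / np.maximum(ds, 1e-12)
    curv_std = float(np.std(curvature, ddof=1))

    area = float(mask.sum())
    props = regionprops(mask.astype(np.uint8))[0]
    major, minor = props.axis_major_length, props.axis_minor_length
    circularity = 4 * np.pi * area / perimeter**2
    return np.array([
        curv_std,
        circularity,
        _safe_div(major, minor),
        perimeter / area,
        _safe_div(perimeter, major),
    ])


# ---------------------------------------------------------------------------
# second-order (GLCM) features


def compute_glcm(image: np.ndarray, region: np.ndarray, direction: str,
                 levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of a region at offset 1.

    Intensities are quantized to ``levels`` gray levels over the region's
    min-max range; only pixel pairs with both members inside the region are
    counted; the count matrix is symmetrized and normalized to sum to 1.
    """
    image = np.asarray(image, dtype=float)
    region = np.asarray(region, dtype=bool)
    if direction not in ("vertical", "horizontal"):
        raise ValueError("direction must be 'vertical' or 'horizontal'")
    vals = image[region]
    if vals.size < 2:
        raise FeatureError("region too small for a co-occurrence matrix")
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((image - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros_like(image, dtype=int)
    dr, dc = (1, 0) if direction == "vertical" else (0, 1)
    a_region = region[: region.shape[0] - dr, : region.shape[1] - dc]
    b_region = region[dr:, dc:]
    both = a_region & b_region
    if not both.any():
        raise FeatureError("region has no co-resident pixel pairs at this offset")
    a = q[: q.shape[0] - dr, : q.shape[1] - dc][both]
    b = q[dr:, dc:][both]
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_descriptors(M: np.ndarray) -> dict[str, float]:
    """The 13 co-occurrence texture statistics used by this framework.

    Entropy-type descriptors use base-2 logarithms except the two
    information measures of correlation, whose classic definitions use
    natural logarithms (the ``1 - exp(-2 dH)`` form).  Correlation I
    (moment form) and correlation II (product form) are both evaluated
    from their literal formulas; for a normalized symmetric matrix they
    coincide algebraically.
    """
    M = np.asarray(M, dtype=float)
    G = M.shape[0]
    i = np.arange(G)[:, None].astype(float)
    j = np.arange(G)[None, :].astype(float)
    px = M.sum(axis=1)
    py = M.sum(axis=0)
    mu_x = float((np.arange(G) * px).sum())
    mu_y = float((np.arange(G) * py).sum())
    sd_x = float(np.sqrt(((np.arange(G) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(G) - mu_y) ** 2 * py).sum()))

    contrast = float(((i - j) ** 2 * M).sum())
    dissimilarity = float((np.abs(i - j) * M).sum())
    energy = float((M ** 2).sum())
    nz = M > 0
    entropy = float(-(M[nz] * np.log2(M[nz])).sum())
    hom1 = float((M / (1.0 + np.abs(i - j))).sum())
    hom2 = float((M / (1.0 + (i - j) ** 2)).sum())
    max_prob = float(M.max())
    if sd_x > 0 and sd_y > 0:
        corr1 = float((((i - mu_x) * (j - mu_y) * M).sum()) / (sd_x * sd_y))
        corr2 = float(((i * j * M).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        corr1 = corr2 = np.nan

    k = np.arange(G).astype(float)
    p_diff = np.zeros(G)
    for d in range(G):
        p_diff[d] = M[np.abs(i - j) == d].sum()
    mu_d = float((k * p_diff).sum())
    diff_var = float(((k - mu_d) ** 2 * p_diff).sum())
    nzd = p_diff > 0
    diff_ent = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())

    # information measures of correlation (natural-log convention)
    pxy = px[:, None] * py[None, :]
    nzm = M > 0
    hxy = float(-(M[nzm] * np.log(M[nzm])).sum())
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(M * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    nzx, nzy = px > 0, py > 0
    hx = float(-(px[nzx] * np.log(px[nzx])).sum())
    hy = float(-(py[nzy] * np.log(py[nzy])).sum())
    denom = max(hx, hy)
    infocorr1 = (hxy - hxy1) / denom if denom > 0 else np.nan
    infocorr2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "contrast": contrast, "correlation1": corr1, "correlation2": corr2,
        "dissimilarity": dissimilarity, "energy": energy, "entropy": entropy,
        "homogeneity1": hom1, "homogeneity2": hom2, "max_probability": max_prob,
        "difference_variance": diff_var, "difference_entropy": diff_ent,
        "infocorr1": infocorr1, "infocorr2": infocorr2,
    }


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class FeatureVector:
    """The 62 features of one lesion, in frozen index order."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (N_FEATURES,):
            raise FeatureError(f"expected {N_FEATURES} features, "
                               f"got {self.values.shape}")

    def __getitem__(self, idx: int) -> float:
        """1-based indexing matching the published feature indices."""
        if not 1 <= idx <= N_FEATURES:
            raise IndexError(f"feature index must be in 1..{N_FEATURES}")
        return float(self.values[idx - 1])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def extract_features(image: np.ndarray, regions: RegionTriplet,
                     levels: int = GLCM_LEVELS) -> FeatureVector:
    """Assemble the full 62-element feature vector in frozen index order."""
    first_order = np.concatenate([
        attenuation_features(image, regions),
        lesion_contrast_features(image, regions),
        boundary_features(image, regions),
        statistical_features(image, regions),
    ])
    shape = shape_features(regions.lesion)
    blocks = []
    for region in (regions.lesion, regions.dermis_under):
        for direction, keys in (("horizontal", GLCM_DESCRIPTORS_H),
                                ("vertical", GLCM_DESCRIPTORS_V)):
            desc = glcm_descriptors(compute_glcm(image, region, direction, levels))
            blocks.append([desc[k] for k in keys])
    values = np.concatenate([first_order, shape] + blocks)
    return FeatureVector(values=values)


def feature_table(images, masks, layers_list, labels=None, ids=None,
                  lane_width: int = 5, dermis_depth: int | None = None,
                  levels: int = GLCM_LEVELS) -> pd.DataFrame:
    """Extract features for a batch of images; one row per image.

    Columns are the 62 frozen feature names, plus ``image_id`` and (when
    given) ``label``.  Features that are undefined for a lesion (NaN) stay
    NaN here; imputation happens at classification time.
    """
    rows = []
    for n, (img, mask, layers) in enumerate(zip(images, masks, layers_list)):
        regions = derive_regions(img, mask, layers, lane_width=lane_width,
                                 dermis_depth=dermis_depth)
        fv = extract_features(img, regions, levels=levels)
        row = {"image_id": ids[n] if ids is not None else n}
        if labels is not None:
            row["label"] = labels[n]
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan
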