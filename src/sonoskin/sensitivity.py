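"""Sensitivity of classification to small segmentation-border changes.

A reference lesion mask is progressively grown or shrunk at selected border
sectors (right edge, bottom edge, both, or the entire border) and the
trained classifier is re-run on the re-derived regions and features at each
step.  The output grid of predictions shows how far the classification is
from flipping when the segmentation wobbles — small border changes at the
wrong place (e.g. across a hyperechoic patch) can flip the predicted class
with a shrink of only a couple of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classify import SVMModel, predict
from .errors import MaskError
from .features import derive_regions, extract_features
from .segmentation import SkinLayers

EDGES = ("right", "bottom", "right+bottom", "all")
_EDGE_DIRECTIONS = {  # outward normal (d_row, d_col) of each named edge
    "right": [(0.0, 1.0)],
    "bottom": [(1.0, 0.0)],
    "right+bottom": [(0.0, 1.0), (1.0, 0.0)],
}


def perturb_mask(mask: np.ndarray, edge: str, amount: int) -> np.ndarray:
    """Grow (``amount`` > 0) or shrink (< 0) a mask at one border sector.

    The sector holds the boundary-ring pixels whose outward normal
    (gradient of a smoothed mask indicator) lies within 45 degrees of the
    named edge direction; ``edge='all'`` uses the full isotropic disk.
    ``amount`` is the structuring-disk radius in pixels, at most 10.
    """
    mask = np.asarray(mask, dtype=bool)
    if edge not in EDGES:
        raise MaskError(f"unknown edge sector {edge!r}")
    if abs(amount) > 10:
        raise MaskError("|amount| must be <= 10 px")
    if amount == 0:
        return mask.copy()
    selem = _disk(abs(amount))
    if amount > 0:
        ring = ndimage.binary_dilation(mask, structure=selem) & ~mask
    else:
        ring = mask & ~ndimage.binary_erosion(mask, structure=selem)
    if edge != "all":
        ring &= _sector(mask, _EDGE_DIRECTIONS[edge])
    out = (mask | ring) if amount > 0 else (mask & ~ring)
    if not out.any():
        raise MaskError("perturbation emptied the mask")
    return out


def _sector(mask: np.ndarray, directions, half_angle_deg: float = 45.0) -> np.ndarray:
    """Pixels whose outward normal is within ``half_angle_deg`` of any of
    the given directions."""
    smooth = ndimage.gaussian_filter(mask.astype(float), sigma=2.0)
    gr, gc = np.gradient(smooth)
    norm = np.hypot(gr, gc)
    with np.errstate(invalid="ignore", divide="ignore"):
        nr = np.where(norm > 1e-9, -gr / norm, 0.0)
        nc = np.where(norm > 1e-9, -gc / norm, 0.0)
    cos_lim = np.cos(np.deg2rad(half_angle_deg))
    sector = np.zeros(mask.shape, dtype=bool)
    for dr, dc in directions:
        sector |= (nr * dr + nc * dc) > cos_lim
    sector &= norm > 1e-9
    return sector


@dataclass(frozen=True)
class SensitivityGrid:
    """Predictions over the (edge, amount) perturbation grid."""

    edges: tuple[str, ...]
    amounts: tuple[int, ...]
    predictions: np.ndarray   # object array, shape (len(edges), len(amounts))
    correct: np.ndarray       # bool, same shape
    reference_prediction: object

    def flips(self, edge: str) -> int:
        """Number of cells in an edge's row that differ from the
        unperturbed prediction."""
        row = self.predictions[self.edges.index(edge)]
        return int(sum(p != self.reference_prediction for p in row))


def border_sensitivity(image: np.ndarray, reference_mask: np.ndarray,
                       model: SVMModel, layers: SkinLayers,
                       true_label, edges=EDGES,
                       amounts=(-4, -3, -2, -1, 0, 1, 2, 3, 4),
                       lane_width: int = 5) -> SensitivityGrid:
    """Classify the lesion under every (edge, amount) border perturbation.

    ``true_label`` is the task-space label of the image (e.g. 1 for the
    positive class of a binary model); a cell is marked correct when the
    model's prediction equals it.  Cells with amount 0 always repeat the
    unperturbed prediction.
    """
    edges = tuple(edges)
    amounts = tuple(amounts)
    preds = np.empty((len(edges), len(amounts)), dtype=object)
    for i, edge in enumerate(edges):
        for j, amount in enumerate(amounts):
            mask = perturb_mask(reference_mask, edge, amount)
            regions = derive_regions(image, mask, layers, lane_width=lane_width)
            fv = extract_features(image, regions)
            label, _ = predict(model, fv.values[None, :])
            preds[i, j] = label[0]
    ref_regions = derive_regions(image, np.asarray(reference_mask, dtype=bool),
                                 layers, lane_width=lane_width)
    ref_fv = extract_features(image, ref_regions)
    ref_label, _ = predict(model, ref_fv.values[None, :])
    correct = np.array([[p == true_label for p in row] for row in preds])
    return SensitivityGrid(edges=edges, amounts=amounts, predictions=preds,
                           correct=correct, reference_prediction=ref_label[0])


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (rr**2 + cc**2) <= radius**2
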