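"""Synthetic B-mode skin phantom generator.

Emulates the layered appearance of high-frequency skin ultrasound — a dark
above-skin (coupling) band, a bright epidermal entry echo, a speckled dermis —
with a single hypoechoic lesion embedded in the dermis.  Lesion appearance is
class-conditional for the three lesion types handled downstream:

* ``nevus`` — homogeneous echotexture, near-elliptical border, no posterior
  shadowing;
* ``BCC``  — moderately heterogeneous echotexture with strong posterior
  acoustic shadowing;
* ``MM``   — markedly heterogeneous echotexture and an irregular border.

Speckle is modelled as multiplicative exponential-intensity noise (the
squared magnitude of a unit-variance complex Gaussian scatterer sum), blurred
by a small Gaussian point-spread function to mimic spatial speckle
correlation.  This is a standard stylised ultrasound texture model, not a
pulse-echo acoustic simulation; see the methods note for what it does and
does not emulate.

Every sample carries its ground-truth lesion mask and layer geometry so the
segmentation, feature and classification stages can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError

CLASSES = ("nevus", "BCC", "MM")


@dataclass(frozen=True)
class ClassAppearance:
    """Class-conditional lesion appearance parameters.

    Parameters
    ----------
    echogenicity : float
        Mean lesion intensity relative to the mean dermis intensity
        (skin lesions are hypoechoic, so values are < 1).
    heterogeneity : float
        Echotexture heterogeneity; 1.0 is the fully-developed correlated
        speckle of the surrounding dermis, larger values add uncorrelated
        multiplicative variance inside the lesion.
    semi_axes : (float, float)
        Ellipse semi-axes in pixels, (axial, lateral).
    irregularity : float
        Maximum radial displacement (pixels) of the sinusoidal border
        perturbation; 0 gives an exact discrete ellipse.
    shadow : float
        Posterior acoustic shadow strength in [0, 1]; 0 disables shadowing.
    """

    echogenicity: float
    heterogeneity: float = 1.0
    semi_axes: tuple[float, float] = (10.0, 18.0)
    irregularity: float = 0.0
    shadow: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.shadow <= 1.0:
            raise PhantomSpecError(f"shadow strength must be in [0,1], got {self.shadow}")
        if self.echogenicity <= 0:
            raise PhantomSpecError("echogenicity must be positive")
        if self.heterogeneity < 1.0:
            raise PhantomSpecError("heterogeneity multiplier must be >= 1")
        if min(self.semi_axes) <= 1:
            raise PhantomSpecError("ellipse semi-axes must exceed 1 px")
        if self.irregularity < 0:
            raise PhantomSpecError("irregularity amplitude must be >= 0")


#: Default class appearances: hypoechoic lesions, with the qualitative
#: class signatures described in the dermatologic-ultrasound literature.
DEFAULT_CLASS_PARAMS: dict[str, ClassAppearance] = {
    "nevus": ClassAppearance(echogenicity=0.35, heterogeneity=1.0,
                             semi_axes=(10.0, 18.0), irregularity=0.5, shadow=0.0),
    "BCC": ClassAppearance(echogenicity=0.40, heterogeneity=1.6,
                           semi_axes=(12.0, 15.0), irregularity=1.5, shadow=0.55),
    "MM": ClassAppearance(echogenicity=0.50, heterogeneity=2.2,
                          semi_axes=(11.0, 16.0), irregularity=4.0, shadow=0.15),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue echogenicity and speckle model of the phantom.

    Depth runs along rows (row 0 = skin surface side); the lateral direction
    runs along columns, as in a clinical B-mode frame.
    """

    image_height: int = 128
    image_width: int = 160
    above_skin_depth: int = 12
    epidermis_depth: int = 8
    #: Mean intensities of the three bands, on the [0, 1] scale.
    above_skin_echo: float = 0.04
    epidermis_echo: float = 0.85
    dermis_echo: float = 0.50
    #: Gaussian PSF sigma (pixels) applied to the raw exponential speckle.
    psf_sigma: float = 0.8
    #: Depth constant (pixels) of the exponential posterior-shadow decay.
    shadow_decay: float = 40.0
    #: Rows that must remain lesion-free at the bottom of the dermis so the
    #: dermis-under-lesion region is never empty.
    dermis_margin: int = 12
    class_params: dict[str, ClassAppearance] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))

    @property
    def dermis_top(self) -> int:
        return self.above_skin_depth + self.epidermis_depth

    def validate(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise PhantomSpecError("phantom images must be at least 64x64")
        if self.above_skin_depth <= 0 or self.epidermis_depth <= 0:
            raise PhantomSpecError("layer band thicknesses must be positive")
        if self.dermis_top >= self.image_height - self.dermis_margin:
            raise PhantomSpecError("no dermis band left below the epidermis")
        for name, params in self.class_params.items():
            if name not in CLASSES:
                raise PhantomSpecError(f"unknown lesion class {name!r}")
            params.validate()


@dataclass(frozen=True)
class PhantomSample:
    """One generated image with its ground truth."""

    image: np.ndarray          # float64 in [0, 1], shape (H, W)
    truth_mask: np.ndarray     # bool, same shape, single 4-connected blob
    #: Per-column band boundary rows: (epidermis_top, dermis_top, dermis_bottom).
    truth_layers: tuple[np.ndarray, np.ndarray, np.ndarray]
    label: str
    seed: int


@dataclass(frozen=True)
class LabeledDataset:
    """A reproducible collection of phantom samples."""

    samples: list[PhantomSample]
    spec: PhantomSpec
    seed: int

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


def _perturbed_ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                            semi_axes: tuple[float, float], irregularity: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Rasterize a radially perturbed ellipse.

    The border radius along each ray is the ellipse radius plus a smooth
    random-phase sinusoidal perturbation (harmonics 2-5) normalised so that
    its maximum absolute displacement equals ``irregularity``.  With zero
    amplitude the result is the exact discrete ellipse (pixel centers with
    normalised radius <= 1).
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    a_ax, a_lat = semi_axes
    theta = np.arctan2(dr, dc)
    radius = np.hypot(dr, dc)
    ellipse_r = 1.0 / np.sqrt((np.sin(theta) / a_ax) ** 2 + (np.cos(theta) / a_lat) ** 2)
    if irregularity > 0:
        harmonics = np.arange(2, 6)
        amps = rng.uniform(0.3, 1.0, size=harmonics.size)
        phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
        pert = np.zeros_like(theta)
        # normalise on a dense angular grid so max displacement == irregularity
        grid = np.linspace(-np.pi, np.pi, 720)
        dense = np.zeros_like(grid)
        for k, a, p in zip(harmonics, amps, phases):
            pert += a * np.sin(k * theta + p)
            dense += a * np.sin(k * grid + p)
        scale = irregularity / max(np.abs(dense).max(), 1e-12)
        boundary = ellipse_r + scale * pert
    else:
        boundary = ellipse_r
    mask = radius <= boundary
    # smooth low-order perturbation keeps the region star-shaped, but guard
    # the invariants anyway: keep the largest 4-connected blob, fill holes
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _speckle(shape: tuple[int, int], psf_sigma: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Correlated multiplicative speckle with unit mean.

    Returns the PSF-blurred exponential field and the raw (uncorrelated)
    exponential field it was built from; the raw field drives the extra
    heterogeneity inside lesions.
    """
    raw = rng.exponential(1.0, size=shape)
    blurred = ndimage.gaussian_filter(raw, sigma=psf_sigma, mode="reflect")
    return blurred, raw


def generate_phantom(spec: PhantomSpec, label: str, seed: int) -> PhantomSample:
    """Generate one phantom image with ground truth.

    Deterministic for a fixed ``(spec, label, seed)``.  The lesion center is
    drawn uniformly over the positions at which the lesion (including its
    irregularity margin) fits inside the dermis band with ``dermis_margin``
    rows to spare below; a spec whose lesion cannot fit raises
    :class:`~sonoskin.errors.PhantomSpecError`.
    """
    spec.validate()
    if label not in CLASSES:
        raise PhantomSpecError(f"unknown lesion class {label!r}")
    params = spec.class_params[label]
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width

    a_ax, a_lat = params.semi_axes
    pad = params.irregularity + 2.0
    top = spec.dermis_top + a_ax + pad
    bottom = h - spec.dermis_margin - a_ax - pad
    left = a_lat + pad + 2.0
    right = w - a_lat - pad - 2.0
    if top >= bottom or left >= right:
        raise PhantomSpecError(
            f"lesion with semi-axes {params.semi_axes} and irregularity "
            f"{params.irregularity} does not fit in the dermis band")
    center = (rng.uniform(top, bottom), rng.uniform(left, right))

    mask = _perturbed_ellipse_mask((h, w), center, params.semi_axes,
                                   params.irregularity, rng)

    # tissue echogenicity map
    echo = np.full((h, w), spec.dermis_echo)
    echo[: spec.above_skin_depth, :] = spec.above_skin_echo
    echo[spec.above_skin_depth: spec.dermis_top, :] = spec.epidermis_echo
    echo[mask] = spec.dermis_echo * params.echogenicity

    blurred, raw = _speckle((h, w), spec.psf_sigma, rng)
    speckle = blurred.copy()
    if params.heterogeneity > 1.0:
        extra = 0.5 * (params.heterogeneity - 1.0) * (raw - 1.0)
        speckle[mask] = np.clip(blurred[mask] * (1.0 + extra[mask]), 0.0, None)

    image = echo * speckle

    if params.shadow > 0:
        thickness = mask.sum(axis=0).astype(float)
        t_max = thickness.max()
        cols = np.nonzero(thickness)[0]
        rows = np.arange(h)[:, None]
        bottoms = np.where(mask.any(axis=0),
                           h - 1 - np.argmax(mask[::-1, :], axis=0), -1)
        for c in cols:
            below = rows[:, 0] > bottoms[c]
            depth = rows[below, 0] - bottoms[c]
            rel = thickness[c] / t_max
            # darkening is strongest immediately under the lesion and fades
            # exponentially with depth (depth-gain compensation recovers the
            # signal), scaled by the lesion thickness crossed in this column
            factor = 1.0 - params.shadow * rel * np.exp(-depth / spec.shadow_decay)
            image[below, c] *= factor

    image = np.clip(image, 0.0, 1.0)

    cols_idx = np.arange(w)
    layers = (np.full_like(cols_idx, spec.above_skin_depth),
              np.full_like(cols_idx, spec.dermis_top),
              np.full_like(cols_idx, h))
    return PhantomSample(image=image, truth_mask=mask, truth_layers=layers,
                         label=label, seed=seed)


def generate_dataset(spec: PhantomSpec, counts: dict[str, int] | tuple[int, int, int],
                     seed: int) -> LabeledDataset:
    """Generate a shuffled labelled dataset.

    ``counts`` gives the number of samples per class, either as a mapping or
    as an ``(n_nevus, n_BCC, n_MM)`` tuple.  Per-sample seeds derive
    deterministically from the master seed, so the dataset is reproducible
    byte for byte and individual samples can be regenerated in isolation.
    """
    if not isinstance(counts, dict):
        counts = dict(zip(CLASSES, counts))
    for name, n in counts.items():
        if name not in CLASSES:
            raise PhantomSpecError(f"unknown lesion class {name!r}")
        if n < 0:
            raise PhantomSpecError("per-class counts must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [name for name in CLASSES for _ in range(counts.get(name, 0))]
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(labels))
    order = rng.permutation(len(labels))
    samples = [generate_phantom(spec, labels[i], int(sample_seeds[i])) for i in order]
    return LabeledDataset(samples=samples, spec=spec, seed=seed)


def plant_hyperechoic_patch(sample: PhantomSample, *, width: int = 3,
                            level: float = 0.95) -> PhantomSample:
    """Return a copy of ``sample`` with a bright patch lining the lesion's
    right inner edge.

    The patch occupies the lesion pixels within ``width`` of the border
    whose outward normal points rightward (within 45 degrees), so shrinking
    the mask's right edge by ``width`` pixels removes it from the lesion
    region entirely — the scenario used to probe how sensitive a trained
    classifier is to small border changes.
    """
    from .sensitivity import _sector  # local import to avoid a cycle

    mask = sample.truth_mask
    d_in = ndimage.distance_transform_edt(mask)
    patch = mask & (d_in <= width) & _sector(mask, [(0.0, 1.0)])
    image = sample.image.copy()
    image[patch] = level
    return replace(sample, image=image)
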