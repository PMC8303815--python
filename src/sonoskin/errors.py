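"""Typed errors raised by the pipeline.

Every failure mode that a caller may want to catch gets its own class;
nothing in the pipeline ever returns a silently-empty mask or NaN-filled
report in place of raising.
"""


class SonoskinError(Exception):
    """Base class for all package errors."""


class PhantomSpecError(SonoskinError):
    """Invalid phantom specification (e.g. lesion does not fit in the dermis)."""


class NormalizationError(SonoskinError):
    """Image cannot be intensity-normalized (constant image)."""


class LayerDetectionError(SonoskinError):
    """Skin-layer extraction failed (no entry-echo band found)."""


class NoLesionFoundError(SonoskinError):
    """No lesion candidate of sufficient size inside the dermis."""


class GrowthFailureError(SonoskinError):
    """Active-contour growing collapsed below the minimum lesion area."""


class MaskError(SonoskinError):
    """A lesion mask violates its invariants."""


class PolygonError(SonoskinError):
    """Degenerate or empty polygon input."""


class RegionError(SonoskinError):
    """Analysis regions (lesion / dermis-under / boundary lane) cannot be derived."""


class FeatureError(SonoskinError):
    """A feature is undefined for the given region geometry."""


class EvaluationError(SonoskinError):
    """Classification / cross-validation setup error (missing class, bad folds...)."""


class ManifestError(SonoskinError):
    """Dataset manifest is missing, malformed, or references absent files."""
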