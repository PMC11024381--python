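"""Exception hierarchy for the tepal-arrangement pipeline.

Stage failures are ordinary, expected events (a flower that cannot be
segmented, a spec the renderer cannot realize); they all derive from
:class:`TepalsError` so callers can catch the package's failures without
swallowing programming errors.
"""


class TepalsError(Exception):
    """Base class for all failures raised by this package."""


class InvalidInputError(TepalsError, ValueError):
    """An input violates a documented precondition (empty image, bad box...)."""


class DetectionFailureError(TepalsError):
    """No flower-like region could be located in the image."""


class SegmentationFailureError(TepalsError):
    """Foreground extraction produced an empty or undefined region.

    Typically signals a foreground/background color collision, where a
    color-model segmenter has no contrast to work with.
    """


class UndefinedMetricError(TepalsError, ValueError):
    """A metric is undefined for the given inputs (e.g. IoU of two empty regions)."""


class TooFewOverlapsError(TepalsError):
    """Fewer overlap points than needed to form a circular sequence (< 3)."""


class CompositionError(TepalsError):
    """Two contour-arc patches could not be superimposed into a synthetic overlap."""


class PatchSynthesisError(TepalsError):
    """The per-flower synthetic patch quota could not be met."""


class RendererInfeasibleError(TepalsError):
    """The requested flower geometry cannot be drawn with only adjacent-tepal overlaps."""


class TrainingFailureError(TepalsError):
    """Meta-training diverged (non-finite loss)."""


class CatalogError(TepalsError, ValueError):
    """An arrangement catalog file is malformed or inconsistent."""


class CorrectionError(TepalsError, ValueError):
    """A manual-correction edit references a point that does not exist."""
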