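"""Exception hierarchy for pathocell.

All errors derive from :class:`PathocellError` so callers can catch the
package's failures with a single except clause; each also derives from the
closest builtin (ValueError/KeyError/RuntimeError) for idiomatic handling.
"""


class PathocellError(Exception):
    """Base class for all pathocell errors."""


class DimensionMismatchError(PathocellError, ValueError):
    """Array shapes or channel counts are incompatible."""


class DegenerateClusteringError(PathocellError, ValueError):
    """Fewer distinct colours than requested clusters."""


class DegenerateThresholdError(PathocellError, ValueError):
    """Otsu thresholding on a constant image."""


class ConfigurationError(PathocellError, ValueError):
    """Invalid or empty configuration interval/value."""


class CoordinateError(PathocellError, ValueError):
    """A pixel coordinate lies outside the image."""


class MissingLabelError(PathocellError, KeyError):
    """Requested label is absent from a label map."""


class SchemaError(PathocellError, ValueError):
    """A feature table does not cover the required column manifest."""


class DegenerateTrainingError(PathocellError, ValueError):
    """Training labels contain a single class."""


class UndefinedROCError(PathocellError, ValueError):
    """ROC requested with only one class present."""


class InsufficientLevelsError(PathocellError, ValueError):
    """Fewer than three distinct cellularity levels in a labelled table."""


class InsufficientDataError(PathocellError, ValueError):
    """Too few matched prediction/reference pairs to evaluate."""


class PlacementError(PathocellError, RuntimeError):
    """Phantom nuclei could not be placed without overlap within the retry budget."""
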