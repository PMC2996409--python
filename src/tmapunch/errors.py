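"""Exception types raised by the tile-classification pipeline."""


class TmaPunchError(Exception):
    """Base class for all package errors."""


class DegenerateImageError(TmaPunchError):
    """Image has too few distinct gray levels / colors to segment."""


class SingularSystemError(TmaPunchError):
    """Calibration anchors coincide; the quadratic transfer is not unique."""


class InvalidResolutionError(TmaPunchError):
    """A physical resolution (um/px) was zero, negative or missing."""


class GridMismatchError(TmaPunchError):
    """A grid was applied to an image of a different size."""


class UndefinedStatisticError(TmaPunchError):
    """A statistic was requested on an empty object list."""


class UndefinedMetricError(TmaPunchError):
    """A confusion-matrix metric has a zero denominator."""
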