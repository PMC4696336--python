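"""Exception types shared across the scoring pipeline."""


class Notch3ScoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Notch3ScoreError):
    """Raster file has an unsupported layout or bit depth."""


class ParameterError(Notch3ScoreError, ValueError):
    """A parameter value is outside its valid range."""


class DimensionError(Notch3ScoreError):
    """Image and mask dimensions do not match."""


class DegenerateInputError(Notch3ScoreError):
    """Input is too small or too uniform for the requested computation."""


class PlacementError(Notch3ScoreError):
    """Deposit placement could not satisfy the non-overlap constraint.

    Attributes
    ----------
    requested, achieved : int
        Number of deposits asked for and number actually placed before
        the retry budget was exhausted.
    """

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} deposits before "
            f"exhausting retries; reduce count, radius or gap"
        )
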