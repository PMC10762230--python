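"""Exception hierarchy for the rotomo pipeline.

Every stage raises a subclass of :class:`RotomoError` so callers can
distinguish pipeline failures from programming errors.
"""


class RotomoError(Exception):
    """Base class for all rotomo pipeline errors."""


class ValidationError(RotomoError, ValueError):
    """A configuration or specification object violates its invariants."""


class NoCellFound(RotomoError):
    """Cell detection found no connected component above the area threshold."""


class SegmentationEmpty(RotomoError):
    """Segmentation produced an empty foreground mask."""


class EmptyFeatureSet(RotomoError):
    """Corner detection found no feature above threshold inside the mask."""


class OrbitDegenerate(RotomoError):
    """A feature track has no lateral variance; its orbit cannot be fitted."""


class FusionGap(RotomoError):
    """No valid feature is available at some frame during track fusion."""

    def __init__(self, frame: int):
        self.frame = frame
        super().__init__(f"no valid feature track at frame {frame}")
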