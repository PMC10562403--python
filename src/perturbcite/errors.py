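"""Exception types shared across the pipeline stages."""


class PerturbCiteError(Exception):
    """Base class for all package-specific errors."""


class DuplicateBarcodeError(PerturbCiteError):
    """Two feature-reference entries share a barcode sequence."""


class MalformedRowError(PerturbCiteError):
    """A feature-reference row is missing required fields."""


class FormatError(PerturbCiteError):
    """An on-disk matrix triple is inconsistent or malformed."""


class EmptyInputError(PerturbCiteError):
    """An operation that requires at least one record received none."""


class UnknownGuideError(PerturbCiteError):
    """A called guide is absent from the guide-to-gene map."""


class MissingReferenceError(PerturbCiteError):
    """The non-targeting reference label has no cells."""


class MissingModalityError(PerturbCiteError):
    """A per-cell score component is unavailable for some cell."""


class EmptySignatureError(PerturbCiteError):
    """A gene signature contains no genes present in the universe."""


class GroupTooSmallError(PerturbCiteError):
    """A differential-expression group has fewer cells than required."""


class EmptyBinError(PerturbCiteError):
    """A screen sorting bin contains no reads."""


class NoNTGuidesError(PerturbCiteError):
    """Z-score ranking requires at least two non-targeting guides."""


class InvalidInputError(PerturbCiteError):
    """Overlap-test inputs violate their constraints."""


class ZeroMarginError(PerturbCiteError):
    """A contingency table has a zero row or column margin."""


class KTooLargeError(PerturbCiteError):
    """k-means requested more clusters than rows."""


class InvalidConfigError(PerturbCiteError):
    """A simulation or pipeline configuration violates its invariants."""


class ConfigError(PerturbCiteError):
    """A pipeline configuration references missing inputs."""


class StageError(PerturbCiteError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
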