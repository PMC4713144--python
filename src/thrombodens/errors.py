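"""Exception hierarchy shared across the pipeline."""


class ThromboDensError(Exception):
    """Base class for all package errors."""


class FormatError(ThromboDensError):
    """A file could not be parsed as a supported volume format."""


class MetadataError(ThromboDensError):
    """Required header metadata (e.g. voxel spacing) is missing or invalid."""


class SeedError(ThromboDensError):
    """A seed point violates its preconditions (outside volume / below threshold)."""


class ConnectivityError(ThromboDensError):
    """No connected path exists between the two seeds inside the threshold region."""


class EmptyResultError(ThromboDensError):
    """A geometric operation mapped every foreground voxel outside the target grid."""


class EmptyMaskError(ThromboDensError):
    """An operation requiring a non-empty mask received an empty one."""


class NoThrombusFoundError(ThromboDensError):
    """No voxel inside the search region falls within the intensity bounds."""


class DegenerateInputError(ThromboDensError):
    """Input is constant / degenerate where variation is required."""


class MaskTooSmallError(ThromboDensError):
    """The mask cannot accommodate even a single ROI sphere."""


class SpecError(ThromboDensError):
    """A phantom specification violates its invariants."""


class SchemaError(ThromboDensError):
    """A tabular input is missing required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class RegistrationWarning(UserWarning):
    """The registration schedule finished without improving the metric."""
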