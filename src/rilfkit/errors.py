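"""Exception hierarchy shared across the package."""


class RilfkitError(Exception):
    """Base class for all package errors."""


class ValidationError(RilfkitError, ValueError):
    """Invalid argument values or malformed inputs."""


class ConfigurationError(RilfkitError):
    """Inconsistent or incomplete pipeline/simulation configuration."""


class SchemaError(ValidationError):
    """A tabular input does not match the expected column schema."""


class DomainError(RilfkitError, ValueError):
    """A quantity lies outside the mathematical domain of an operation."""


class FitError(RilfkitError, RuntimeError):
    """A model fit failed to converge or the data carry no signal."""


class SegmentationError(RilfkitError):
    """Lung segmentation produced an empty or invalid mask."""


class SeedPointError(SegmentationError):
    """The region-growing seed voxel lies outside the HU window."""


class GeometryError(RilfkitError):
    """A synthetic phantom geometry cannot be constructed."""
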