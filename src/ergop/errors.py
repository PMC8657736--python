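"""Exception hierarchy shared across the package."""


class ErgopError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(ErgopError, ValueError):
    """A trace file violates the on-disk format or a trace invariant."""


class ManifestValidationError(ErgopError, ValueError):
    """A cohort manifest violates the sweep/eye completeness rules."""


class ParameterError(ErgopError, ValueError):
    """Invalid simulation or filter parameters."""


class CalibrationError(ErgopError, RuntimeError):
    """The b-wave/a-wave calibration cannot reach its amplitude targets."""


class FeatureExtractionError(ErgopError, ValueError):
    """An a- or b-wave could not be located in the search window."""


class DegenerateDataError(ErgopError, ValueError):
    """Statistical input carries no variance to test."""


class ConfigError(ErgopError, ValueError):
    """Unknown or ill-typed key in a run configuration."""
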