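"""Exception hierarchy shared across the pipeline."""


class AupdScanError(Exception):
    """Base class for all package errors."""


class FormatError(AupdScanError):
    """A file or record does not conform to the expected dialect."""


class DataValueError(AupdScanError, ValueError):
    """A value violates a domain invariant (e.g. BAF outside [0, 1])."""


class AssayError(AupdScanError):
    """A wet-lab measurement is unusable (e.g. both MS-PCR peaks zero)."""


class InsufficientDataError(AupdScanError):
    """Too few usable observations to run an analysis."""


class ModelInconsistencyError(AupdScanError):
    """Measurements violate a model identity beyond tolerance."""


class ConfigError(AupdScanError):
    """Invalid or incomplete run configuration."""
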