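"""Exception hierarchy shared across the package."""


class AEPError(Exception):
    """Base class for all package errors."""


class ValidationError(AEPError):
    """A record or table violates a structural invariant."""


class RecordParseError(AEPError):
    """A waveform file could not be parsed in the declared dialect."""


class ConfigurationError(AEPError):
    """A configuration value is inconsistent or out of range."""


class DataError(AEPError):
    """Input data are inconsistent with what an operation requires."""


class IntegrityError(AEPError):
    """Internal consistency check failed (indicates an upstream bug)."""


class InsufficientDataError(DataError):
    """Too few observations to carry out a statistical comparison."""
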