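"""Exception hierarchy."""


class BurstlinkError(Exception):
    """Base class for all package errors."""


class SchemaError(BurstlinkError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(BurstlinkError):
    """Referential integrity between tables is violated."""


class ConfigError(BurstlinkError):
    """A configuration value violates a model invariant."""


class ReferenceError_(BurstlinkError):
    """Too few spots to estimate the single-molecule reference intensity."""


class CalibrationError(BurstlinkError):
    """Too few bi-allelic pairs to calibrate the same-allele threshold."""
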