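"""Exception hierarchy shared across the toolkit.

Every error raised deliberately by this package derives from :class:`VtcError`,
so the command-line layer can catch one type and print a one-line diagnostic.
"""


class VtcError(Exception):
    """Base class for all errors raised by this package."""


class VcfParseError(VtcError):
    """A VCF file could not be parsed; the message names the offending line."""


class UnknownSampleError(VtcError):
    """A requested sample ID is not present in the pool; lists available IDs."""


class VcfValidationError(VtcError):
    """An emitted VCF failed strict re-validation."""


class DslSyntaxError(VtcError):
    """Malformed operation token; the message carries the character position."""


class DslResolutionError(VtcError):
    """An operand references a pool or operation ID that does not resolve."""


class DslArityError(VtcError):
    """An operation was given the wrong number of operands."""


class PhenotypeError(VtcError):
    """Malformed phenotype table."""


class AssociationError(VtcError):
    """Association analysis cannot be performed on the given inputs."""


class ConfigError(VtcError):
    """Invalid synthetic-data generator configuration."""
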