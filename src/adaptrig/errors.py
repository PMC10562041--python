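"""Exception hierarchy.

Three branches matter to callers (and to the CLI exit codes): configuration
problems, data problems, and everything else.
"""


class AdaptrigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdaptrigError):
    """Invalid run configuration, unknown site, bad generator spec."""


class DomainError(AdaptrigError, ValueError):
    """Argument outside its mathematical domain (e.g. x% not in (0, 100])."""


class UsageError(AdaptrigError):
    """An operation applied to an object it does not apply to."""


class DataError(AdaptrigError):
    """Problems with input data content."""


class EmptyStructureError(DataError):
    """Structure mask selects no voxels."""


class CongruenceError(DataError):
    """Dose grid and structure mask shapes disagree."""


class DataCompletenessError(DataError):
    """A structure required by a valid metric is missing."""


class SchemaError(DataError):
    """Tabular input does not conform to the documented CSV dialect."""


class DataIntegrityError(DataError):
    """Table content violates an invariant (status/value consistency, ...)."""
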