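"""Exception hierarchy shared across the package."""


class SSMetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SSMetaError):
    """A dataset is missing mandatory columns or is otherwise malformed."""


class ConfigurationError(SSMetaError):
    """A simulation or analysis configuration is internally inconsistent."""


class DegenerateInputError(SSMetaError):
    """Inputs are formally valid but lead to an undefined quantity
    (e.g. zero pooled standard deviation)."""


class NotApplicableError(SSMetaError):
    """The requested effect measure is undefined for this record
    (e.g. a ratio measure with a non-positive mean); the record should
    be skipped with a log entry rather than aborting the run."""


class UnsupportedInputError(SSMetaError):
    """A conversion has no unique mapping for these inputs
    (e.g. an F statistic with numerator df > 1)."""


class DesignError(SSMetaError):
    """The fixed-effect design is rank deficient or refers to unknown
    moderator levels."""
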