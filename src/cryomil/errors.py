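"""Exception types shared across the package."""


class CryomilError(Exception):
    """Base class for package errors."""


class ConfigurationError(CryomilError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DimensionMismatchError(CryomilError, ValueError):
    """Array shapes inconsistent between two pipeline stages."""


class EmptyBagError(CryomilError, ValueError):
    """A slide bag with zero patches reached the classifier."""


class DegenerateInputError(CryomilError, ValueError):
    """A statistic was requested on inputs it is undefined for (e.g. one class)."""


class SchemaVersionError(CryomilError, ValueError):
    """A stored cohort or model was written with an incompatible schema version."""
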