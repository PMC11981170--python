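"""Exception hierarchy shared across the package."""


class MrsiNetError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MrsiNetError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(MrsiNetError, ValueError):
    """A configuration object or file is inconsistent."""


class UnknownMetaboliteError(MrsiNetError, KeyError):
    """A metabolite name is not present in the basis set."""


class DataError(MrsiNetError, ValueError):
    """A dataset violates a contract (empty split, single class, ...)."""


class DivergenceError(MrsiNetError, RuntimeError):
    """Training produced a non-finite loss."""


class SchemaError(MrsiNetError, ValueError):
    """A stored dataset file does not match the expected schema."""


class DataIntegrityError(MrsiNetError, ValueError):
    """A stored dataset file is corrupt or contains non-finite payload."""
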