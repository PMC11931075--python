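"""Exception hierarchy shared across the package."""


class MirseedError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirseedError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(MirseedError, ValueError):
    """A parsed value violates a domain invariant."""


class ContractError(MirseedError, RuntimeError):
    """An operation was called outside its stated preconditions."""


class ConfigError(MirseedError, ValueError):
    """A run configuration is incomplete or inconsistent."""
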