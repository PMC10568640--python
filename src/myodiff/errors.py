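"""Exception hierarchy shared across the package."""


class MyodiffError(Exception):
    """Base class for all package-specific errors."""


class FcsFormatError(MyodiffError):
    """A file does not conform to the FCS layout this package reads."""


class UnsupportedFormatError(FcsFormatError):
    """Structurally valid FCS, but a dialect we deliberately do not read
    (e.g. ASCII or double-precision data, non-list-mode)."""


class FcsParseError(FcsFormatError):
    """Malformed HEADER or TEXT segment; carries the byte offset at fault."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class IntegrityError(FcsFormatError):
    """Declared metadata disagrees with the actual DATA segment."""


class ChannelResolutionError(MyodiffError, KeyError):
    """A requested channel name does not resolve in a sample."""


class ConfigurationError(MyodiffError, ValueError):
    """An analysis or simulation configuration is invalid or incomplete."""


class InsufficientDataError(MyodiffError):
    """Too few events to carry out the requested estimate."""


class DegenerateDistributionError(MyodiffError):
    """Density estimation requested on fewer than two distinct values."""


class TransformDomainError(MyodiffError, ValueError):
    """Inverse transform requested outside the transform's image."""
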