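"""Exception types shared across the package."""


class TetherlinkError(Exception):
    """Base class for all package-specific errors."""


class StarFormatError(TetherlinkError, ValueError):
    """A STAR document lacks a required block or column."""


class StarParseError(TetherlinkError, ValueError):
    """A STAR cell could not be converted to the expected type."""


class ParameterError(TetherlinkError, ValueError):
    """A numeric parameter is outside its valid domain."""


class AlphabetError(TetherlinkError, ValueError):
    """A sequence contains a character outside the allowed alphabet."""


class UndefinedModeError(TetherlinkError, ValueError):
    """The mode of an empty distance distribution was requested."""
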