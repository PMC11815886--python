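"""Exception hierarchy used across the package."""


class PairclassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PairclassError):
    """A file does not match the documented schema (missing columns, bad header)."""


class ParseError(PairclassError):
    """A cell inside an otherwise well-formed file could not be parsed."""


class ValidationError(PairclassError):
    """An in-memory value violates a domain invariant."""


class GeneLookupError(PairclassError, KeyError):
    """A requested gene symbol is not present in a matrix."""
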