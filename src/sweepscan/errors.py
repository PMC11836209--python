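"""Exception hierarchy.

All package errors derive from :class:`SweepscanError` so callers (and the
CLI) can distinguish user/data problems from genuine bugs.
"""


class SweepscanError(Exception):
    """Base class for all errors raised by sweepscan."""


class ConfigurationError(SweepscanError):
    """An invalid parameter or simulation configuration field."""


class DataError(SweepscanError):
    """Input data violate a contract (e.g. >2 alleles at a locus)."""


class DomainError(SweepscanError):
    """A request falls outside the mapped genomic domain."""


class ParseError(SweepscanError):
    """A file could not be parsed; message carries the line number."""
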