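"""Exception hierarchy for the mtrc package.

All package errors derive from :class:`MtrcError`, so callers can catch one
base class. The subclasses also derive from :class:`ValueError` so that code
written against generic validation idioms keeps working.
"""


class MtrcError(Exception):
    """Base class for all errors raised by mtrc."""


class FormatError(MtrcError, ValueError):
    """A file on disk is structurally malformed (duplicate ids, bad cells)."""


class ConfigError(MtrcError, ValueError):
    """A configuration value (sample roles, simulation settings) is invalid."""


class DesignError(MtrcError, ValueError):
    """A mixture design violates its invariants (e.g. no unique 1:1 component)."""


class DomainError(MtrcError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class CoverageError(MtrcError, ValueError):
    """A required probe is absent from the matrix or ratio table."""


class PairingError(MtrcError, ValueError):
    """Mix1/Mix2 technical replicates cannot be paired by replicate index."""
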