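"""Exception hierarchy.

All library errors derive from :class:`SpecmonError` so callers (and the CLI,
which maps them to exit codes) can catch one base class.
"""

from __future__ import annotations


class SpecmonError(Exception):
    """Base class for all specmon errors."""


class ValidationError(SpecmonError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(SpecmonError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class NegativeIntensityError(ValidationError):
    """Intensities are negative beyond tolerance; Jaccard is inappropriate.

    Carries the fraction of offending points so the caller can decide whether
    to fall back to cross-correlation similarity.
    """

    def __init__(self, message: str, fraction: float):
        super().__init__(message)
        self.fraction = float(fraction)
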