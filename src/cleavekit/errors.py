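"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`CleavekitError` subclasses map to
exit code 1 (data/domain problems); usage errors are handled by click (code 2).
"""

from __future__ import annotations


class CleavekitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CleavekitError, ValueError):
    """An input value violates a mathematical or physical precondition.

    The message names the offending field.
    """


class DataError(CleavekitError, ValueError):
    """A dataset is structurally unusable (empty, too few points, ...)."""


class UnidentifiableError(DataError):
    """The requested quantity cannot be identified from the data given
    (e.g. a rate from fully saturated time points)."""


class CalibrationError(DataError):
    """A standard curve cannot be built from the supplied standards."""


class ComparisonError(CleavekitError, ValueError):
    """Two measurements were taken under different conditions and must not
    be compared; the message lists the differing metadata fields."""


class IncompleteGridError(DataError):
    """A cross-reactivity grid is missing protease/substrate cells; the
    message lists the absent pairs."""


class ParseError(DataError):
    """A workbench file does not conform to its CSV dialect; the message
    names the file, line and column."""


class ComputationError(CleavekitError, RuntimeError):
    """A numerical routine failed (e.g. ODE step-size collapse); carries
    the last successfully reached time where applicable."""

    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time
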