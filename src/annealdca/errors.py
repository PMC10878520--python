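"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage/config errors exit 2, data errors
exit 3, numeric failures exit 4.
"""


class AnnealDCAError(Exception):
    """Base class for all package errors."""


class DataError(AnnealDCAError):
    """Malformed, empty, or inconsistent input data."""


class AlignmentError(DataError):
    """Sequences of unequal length where an alignment is required."""


class AlphabetError(DataError):
    """A sequence contains a character outside the chosen alphabet."""


class SizeError(AnnealDCAError):
    """Problem size exceeds a hard guard (e.g. exhaustive enumeration)."""


class UnsupportedModelError(AnnealDCAError):
    """Operation undefined for this model family (e.g. contact scores on an
    independent-site model)."""


class NumericError(AnnealDCAError):
    """Numerical failure (degenerate weights, non-finite objective)."""
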