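"""Exception hierarchy.

Errors are split so callers (and the CLI exit-code mapping) can distinguish
malformed input, insufficient seed coverage, iterative-solver failure, and
numerical breakdown.
"""


class QWPrioError(Exception):
    """Base class for all package errors."""


class InputFormatError(QWPrioError):
    """Malformed or degenerate user input (files, parameters, shapes)."""


class SeedCoverageError(QWPrioError):
    """Too few seed genes map into the network to proceed."""


class ConvergenceError(QWPrioError):
    """An iterative solver failed to converge within its iteration cap."""


class NumericError(QWPrioError):
    """Non-finite values or numerical breakdown during propagation."""
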