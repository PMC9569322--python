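"""Exception hierarchy.

All validation failures raise :class:`InvalidArgumentError` (a ``ValueError``)
so callers can catch either the package-specific or the builtin type.
"""

from __future__ import annotations


class MemquenchError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MemquenchError, ValueError):
    """Non-finite, negative, or otherwise physically impossible input."""


class SchemaError(MemquenchError, ValueError):
    """A CSV file does not match the expected column schema."""


class ValidationError(MemquenchError, ValueError):
    """Loaded data violates a type invariant; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class OutOfRangeError(MemquenchError, ValueError):
    """A requested quantity is unreachable (e.g. unattainable saturation)."""


class FitFailureError(MemquenchError, RuntimeError):
    """Optimizer failed to converge.

    Carries the last parameter iterate and, when available, the
    goodness-of-fit at that iterate and a fallback estimate.
    """

    def __init__(self, message: str, last_params=None, gof=None, fallback=None):
        super().__init__(message)
        self.last_params = last_params
        self.gof = gof
        self.fallback = fallback
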