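"""Shared sentinel and exception hierarchy."""

from __future__ import annotations


class _NoCrossing:
    """Singleton marking an amplification curve that never reaches its threshold.

    A well whose fluorescence stays below the user-supplied threshold for the
    whole run has no threshold cycle; downstream it is classified as
    "none detected". Serialized as an empty ``ct`` field in the merged table.
    """

    _instance = None

    def __new__(cls) -> "_NoCrossing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_CROSSING"

    def __reduce__(self):
        return (_NoCrossing, ())


NO_CROSSING = _NoCrossing()


class QpcrMapError(Exception):
    """Base class for all qpcrmap errors."""


class StructureError(QpcrMapError):
    """A raw-run file does not match its platform descriptor's layout."""


class EmptyRunError(QpcrMapError):
    """No well in a raw-run file matched the descriptor's well-label pattern."""


class CurveParseError(QpcrMapError):
    """A serialized fluorescence string contains a non-numeric token."""

    def __init__(self, message: str, token_index: int | None = None):
        super().__init__(message)
        #: 1-based position of the offending token, when known.
        self.token_index = token_index


class SchemaError(QpcrMapError):
    """A tabular input is missing required columns or has mismatched columns."""


class MergeError(QpcrMapError):
    """Raw wells and metadata rows could not be joined as requested."""


class KeyCollisionError(MergeError):
    """Duplicate run_location primary keys within one metadata table."""
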