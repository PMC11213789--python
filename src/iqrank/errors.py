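"""Exception hierarchy shared across the package."""


class IQRankError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IQRankError, ValueError):
    """Invalid input: duplicate ids, bad shapes, out-of-range parameters."""


class ProtocolError(IQRankError, RuntimeError):
    """An oracle or caller answered outside the offered pair.

    Carries ``record_index``, the 1-based comparison at which the
    protocol was violated.
    """

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class SessionStateError(IQRankError, RuntimeError):
    """Operation called on a session in the wrong state."""


class AlignmentError(IQRankError, ValueError):
    """Score sets across observers or sessions do not cover the same items.

    Carries ``difference``, the symmetric difference of the item sets.
    """

    def __init__(self, message: str, difference: set | None = None):
        super().__init__(message)
        self.difference = difference or set()


class CompositionError(IQRankError, ValueError):
    """A dataset composition table cannot be satisfied by the scan pool."""


class UndefinedEstimateError(IQRankError, ValueError):
    """The agreement estimate is undefined (e.g. a constant ratings matrix)."""
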