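"""Exception types shared across the package."""


class CinegateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CinegateError, ValueError):
    """A configuration or parameter value violates its invariants."""


class InvalidInputError(CinegateError, ValueError):
    """An input signal or data structure is unusable for the requested operation."""


class ScanTimeoutError(CinegateError, RuntimeError):
    """The scan state machine ran out of gating signal before completing.

    Carries the phase-encode indices that were still pending.
    """

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []
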