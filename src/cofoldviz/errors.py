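"""Exception hierarchy shared across the package."""


class CofoldvizError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryFormatError(CofoldvizError):
    """Raised for malformed trajectory files.

    ``line`` is the 1-based file line number of the offending row, or
    ``None`` for file-level problems (missing header, missing column).
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class StructureError(CofoldvizError):
    """Raised for invalid dot-bracket strings.

    ``position`` is the 1-based string position where matching failed,
    or ``None`` when the error is not positional.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)
        self.position = position


class ParameterError(CofoldvizError, ValueError):
    """Raised when a user-supplied parameter is out of its valid range."""
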