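"""Exception hierarchy.

Exit-code mapping used by the CLI: InputError -> 2, StageError -> 3.
"""


class CellCtError(Exception):
    """Base class for all package errors."""


class InputError(CellCtError):
    """Malformed input file, bad identifier, or invalid parameter."""


class StageError(CellCtError):
    """An operation was invoked at the wrong pipeline stage."""

    def __init__(self, operation: str, expected: tuple, actual: str):
        self.operation = operation
        self.expected = tuple(expected)
        self.actual = actual
        super().__init__(
            f"{operation!r} requires stage in {sorted(self.expected)}, "
            f"but experiment is at stage {actual!r}"
        )
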