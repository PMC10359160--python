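"""Exception types shared across the package."""


class PlanCTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlanCTError, ValueError):
    """A file or array does not have the expected structure."""


class GridMismatchError(PlanCTError, ValueError):
    """Two objects that must share a sampling grid do not."""


class DegenerateInputError(PlanCTError, ValueError):
    """An input is structurally valid but empty/degenerate for the operation."""


class TrainingDivergedError(PlanCTError, RuntimeError):
    """A loss became non-finite during optimization.

    Carries a ``state`` dict (last step index, last finite losses) so callers
    can dump diagnostics.
    """

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}
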