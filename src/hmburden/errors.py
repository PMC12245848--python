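"""Exception hierarchy shared across the package."""


class HmBurdenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HmBurdenError, ValueError):
    """Invalid configuration (bad mix fractions, unknown grouping, bad scenario...)."""


class DataError(HmBurdenError, ValueError):
    """Input tables are structurally fine but semantically unusable (missing rows, misaligned panels)."""


class SchemaError(DataError):
    """An input file does not conform to the expected tabular dialect."""


class DomainError(HmBurdenError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation."""


class ShapeError(HmBurdenError, ValueError):
    """Array dimensions do not line up."""


class DegenerateInputError(HmBurdenError, ValueError):
    """Input is valid but degenerate for the requested operation (e.g. all-equal quintile values)."""


class ConvergenceError(HmBurdenError, RuntimeError):
    """Iterative fit failed to converge; carries diagnostic info in args."""


class PipelineStageError(HmBurdenError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
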