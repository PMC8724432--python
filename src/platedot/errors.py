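"""Exception hierarchy for the platedot pipeline."""


class PlateDOTError(Exception):
    """Base class for all platedot errors."""


class GeometryError(PlateDOTError):
    """Invalid probe or mesh geometry (non-positive dimension, off-plate source, ...)."""


class InvalidInputError(PlateDOTError):
    """Structurally invalid input (mask length mismatch, bad arguments)."""


class DivisionHazardError(PlateDOTError):
    """A calibration denominator is zero / below the amplitude floor."""

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class NoDataError(PlateDOTError):
    """An operation received an empty retained pair / class set."""


class SelectionFailureError(PlateDOTError):
    """Ring peeling exhausted the grid without meeting the CoV threshold."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report or []


class UnsupportedInputError(PlateDOTError):
    """Input outside an operation's contract (e.g. heterogeneous medium for the
    homogeneous-slab analytic oracle)."""


class SolverError(PlateDOTError):
    """Forward FEM system could not be assembled or factorized."""


class UnmixingConfigurationError(PlateDOTError):
    """Spectral unmixing is underdetermined or rank deficient."""


class RegionError(PlateDOTError):
    """An empty or invalid node region was supplied to a summary operation."""


class MetricFailureError(PlateDOTError):
    """An image profile does not contain the requested number of peaks."""


class InsufficientPhotonsError(PlateDOTError):
    """Monte Carlo run detected zero weight at a retained source-detector pair."""

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class PhantomSpecError(PlateDOTError):
    """Phantom specification is inconsistent (inclusion outside the slab, ...)."""


class PresetLookupError(PlateDOTError, KeyError):
    """Unknown scenario preset name."""


class ValidationError(PlateDOTError):
    """Pipeline configuration failed validation; collects every problem found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


class PipelineStageError(PlateDOTError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
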