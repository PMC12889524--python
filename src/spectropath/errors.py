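"""Exception types shared across the package."""


class SpectropathError(Exception):
    """Base class for package errors."""


class EmptyGraphError(SpectropathError):
    """No grid cell passed the tissue threshold."""


class ConvergenceFailureError(SpectropathError):
    """Sparse eigensolver failed and no dense fallback was possible."""


class SingleClassError(SpectropathError):
    """A training set or fold contains only one class."""


class MissingBlockError(SpectropathError):
    """A descriptor block required by the config was not supplied."""


class InsufficientBandsError(SpectropathError):
    """Fewer than two positive-energy bands for a log-log slope."""


class AllZeroEnergyError(SpectropathError):
    """Every spectral band has zero energy."""


class DuplicatePositionsError(SpectropathError):
    """Two spots share identical coordinates on one slide."""


class TooFewGroupsError(SpectropathError):
    """Not enough groups for the requested number of folds."""


class DegenerateSampleError(SpectropathError):
    """TOST needs n >= 2 and positive spread."""


class StageError(SpectropathError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")
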