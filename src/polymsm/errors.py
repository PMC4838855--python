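"""Exception hierarchy for polymsm.

Every raised error derives from :class:`PolymsmError` so callers can catch
pipeline failures with a single except clause while tests can assert on the
specific failure mode.
"""


class PolymsmError(Exception):
    """Base class for all polymsm errors."""


class InvalidParameterError(PolymsmError, ValueError):
    """A geometry/simulation parameter is out of its valid range."""


class IntegrationBlowupError(PolymsmError, FloatingPointError):
    """A Langevin step produced a non-finite coordinate."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration produced a non-finite coordinate at step {step}")


class InvalidChainError(PolymsmError, ValueError):
    """A transition matrix is not row-stochastic."""


class InvalidCorrelationError(PolymsmError, ValueError):
    """A correlation matrix is not symmetric PSD with unit diagonal."""


class AlignmentDegenerateError(PolymsmError, ValueError):
    """Fit group is collinear/coincident; the Kabsch rotation is underdetermined."""


class InsufficientFramesError(PolymsmError, ValueError):
    """An ensemble operation needs more frames than were supplied."""


class DegenerateReferenceError(PolymsmError, ValueError):
    """The pre/frayed reference points coincide; the transition index is undefined."""


class EmptyInputError(PolymsmError, ValueError):
    """An operation received an empty collection."""


class ZeroVarianceError(PolymsmError, ValueError):
    """A selection group has zero total fluctuation."""

    def __init__(self, group: str):
        self.group = group
        super().__init__(f"group {group!r} has zero total fluctuation")


class UnknownSelectionError(PolymsmError, KeyError):
    """A named selection group does not exist."""


class InvalidKError(PolymsmError, ValueError):
    """k outside [1, n_frames] for k-centers."""


class UnknownMetricError(PolymsmError, ValueError):
    """Unsupported clustering metric."""


class IncompatibleFramesError(PolymsmError, ValueError):
    """Frames do not live in the decomposition's metric space."""


class NoTransitionsError(PolymsmError, ValueError):
    """No transition pair could be counted (trajectories shorter than the lag)."""


class NonErgodicError(PolymsmError, ValueError):
    """The chain (or a count matrix) is not irreducible."""


class DegenerateSpectrumError(PolymsmError, ValueError):
    """Eigenvalue gap at the requested number of macrostates is numerically zero."""


class InvalidLumpingError(PolymsmError, ValueError):
    """A lumping has an empty macrostate or mismatched dimensions."""


class EmptyMacrostateError(PolymsmError, ValueError):
    """A macrostate contains no frames."""


class UnreachableTargetError(PolymsmError, ValueError):
    """The MFPT target set is unreachable from some states."""

    def __init__(self, states):
        self.states = list(states)
        super().__init__(f"target set unreachable from states {self.states}")


class InvalidDurationError(PolymsmError, ValueError):
    """Requested trajectory duration is shorter than one lag time."""


class InvalidSetsError(PolymsmError, ValueError):
    """TPT source/sink sets overlap or are empty."""


class NoPathError(PolymsmError, ValueError):
    """No reactive pathway connects the source to the sink."""


class InsufficientCoverageError(PolymsmError, ValueError):
    """Pathway decomposition covers too little of the total flux to classify."""


class IncompleteRunError(PolymsmError, FileNotFoundError):
    """A pipeline run directory is missing a required artifact."""


class PipelineConfigError(PolymsmError, ValueError):
    """Pipeline configuration failed validation."""
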