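"""Exception hierarchy for the pipeline."""


class MinetkitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MinetkitError):
    """Input file could not be parsed."""


class ValidationError(MinetkitError):
    """A domain object violates its invariants."""


class ArchiveLayoutError(FormatError):
    """Model archive does not contain files at its top level."""


class ParameterError(MinetkitError):
    """An operation parameter is out of its admissible range."""


class EmptyGraphError(MinetkitError):
    """A model yields no internal metabolite nodes."""


class ObjectiveNotFoundError(MinetkitError):
    """The requested objective reaction does not exist in the model."""


class FluxError(MinetkitError):
    """An LP stage failed (infeasible/unbounded/numerical)."""


class CompletenessError(MinetkitError):
    """A pairwise record table does not cover all ordered pairs."""


class NormalizationError(MinetkitError):
    """Matrix values are outside the range required by the consumer."""


class InsufficientSpectrumError(MinetkitError):
    """Too few distinct eigenvalues to unfold a spectrum."""


class DegenerateScaleError(MinetkitError):
    """A scale estimate (sd or MAD) is zero."""


class ThresholdError(MinetkitError):
    """A threshold retains no edges or cannot be applied."""
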