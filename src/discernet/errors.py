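"""Exception hierarchy shared across the package."""


class DiscernetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DiscernetError):
    """Input value outside its documented domain (e.g. a DISCERN score not in 1..5)."""


class EmptyDocument(DiscernetError):
    """HTML with no visible text after cleaning."""


class StratificationError(DiscernetError):
    """A class has too few members to fill every fold."""


class DegenerateLabelsError(DiscernetError):
    """An operation that needs both classes received only one."""


class ShapeError(DiscernetError):
    """Array dimensions do not conform to the declared parameter shapes."""


class EmptySequenceError(DiscernetError):
    """An encoder or pooling step received a zero-length sequence."""


class NumericalError(DiscernetError):
    """Non-finite values where finite ones are required."""


class BackendUnavailableError(DiscernetError):
    """A requested embedding backend (or its model files) is not installed."""


class AlignmentError(DiscernetError):
    """Subword-to-token alignment leaves an original token with no subwords."""


class DivergenceError(DiscernetError):
    """Training produced a non-finite loss; carries the trace so far."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ConfigError(DiscernetError):
    """Invalid or incomplete configuration (empty search space, missing lexicon...)."""


class FeatureError(DiscernetError):
    """Feature extraction produced an unusable matrix (e.g. empty vocabulary)."""


class CoverageError(DiscernetError):
    """Selective prediction left no covered documents to score."""


class ExplainabilityUnavailableError(DiscernetError):
    """Attention-based explanations requested from an attention-free (HE) model."""


class GeneratorConsistencyError(DiscernetError):
    """Synthetic-corpus config would leak trigger templates into the noise vocabulary."""
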