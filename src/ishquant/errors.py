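"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`DataError` maps to 3, :class:`ModelError` to 4.
"""


class ISHQuantError(Exception):
    """Base class for all package errors."""


class FormatError(ISHQuantError):
    """An input file could not be read in a supported format."""


class ParameterError(ISHQuantError, ValueError):
    """A parameter is outside its valid range."""


class DataError(ISHQuantError):
    """Input data violates a precondition (missing classes, empty sets...)."""


class TrainingError(DataError):
    """Classifier training preconditions not met."""


class AnalysisError(DataError):
    """Statistical analysis preconditions not met (e.g. single-class ROC)."""


class HeterogeneityError(DataError):
    """Heterogeneity analysis preconditions not met (e.g. no CEP anchors)."""


class GenerationError(DataError):
    """Synthetic data generation infeasible for the requested spec."""


class ModelError(ISHQuantError):
    """A trained model is unusable or incompatible with the input."""
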