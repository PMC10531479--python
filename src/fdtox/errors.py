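"""Exception hierarchy.

Every contract violation in the library raises one of these named errors so
callers can distinguish bad configuration from bad data from bad state.
"""


class FdtoxError(Exception):
    """Base class for all library errors."""


class ConfigurationError(FdtoxError):
    """Invalid generator or pipeline configuration (bad motif, bad sizes)."""


class GenerationError(FdtoxError):
    """Structure assembly failed (e.g. attachment-site exhaustion)."""


class ParseError(FdtoxError):
    """A SMILES string could not be parsed or sanitized."""


class DescriptorError(FdtoxError):
    """Descriptor computation failed (e.g. element missing from a table)."""


class DomainError(FdtoxError):
    """Input outside an operation's mathematical domain (empty molecule)."""


class OptimizationError(FdtoxError):
    """Monte-Carlo weight optimization cannot proceed (no active attributes)."""


class ParameterError(FdtoxError):
    """Out-of-range hyperparameter (grid_n < 1, n <= p+1, ...)."""


class DataError(FdtoxError):
    """Missing values or malformed rows in an input table."""


class DimensionError(FdtoxError):
    """Shape mismatch between a model and the data handed to it."""


class StateError(FdtoxError):
    """Operation requires a trained/fitted model that is not available."""


class MetricError(FdtoxError):
    """A statistic is undefined for the input (constant response column)."""


class SingularityError(FdtoxError):
    """Rank-deficient design matrix."""


class RegistryError(FdtoxError):
    """Model-registry construction failed (missing predictor columns)."""


class JoinError(FdtoxError):
    """Compound-id mismatch or duplication when aligning tables."""


class LoadError(FdtoxError):
    """An alert library or data file failed to load."""
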