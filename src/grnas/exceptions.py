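"""Exception hierarchy for grnas.

All package errors derive from :class:`GrnasError` so callers can catch one
base type; the subclasses mirror the pipeline stages they protect.
"""


class GrnasError(Exception):
    """Base class for all grnas errors."""


class FormatError(GrnasError, ValueError):
    """Malformed input file (expression CSV, edge list, TF list)."""


class ConfigurationError(GrnasError, ValueError):
    """Invalid configuration value or combination."""


class PreprocessingError(GrnasError, ValueError):
    """A preprocessing step produced an empty or invalid result."""


class StatisticalError(GrnasError, ValueError):
    """Too little data for a statistical procedure."""


class DatasetError(GrnasError, ValueError):
    """Graph/split assembly failure (no usable edges, empty universe, ...)."""


class NumericError(GrnasError, ArithmeticError):
    """Non-finite values encountered during model computation."""


class MetricError(GrnasError, ValueError):
    """Metric undefined for the given labels (e.g. single-class input)."""


class ContractError(GrnasError, ValueError):
    """An internal call contract was violated (shape/length mismatch)."""
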