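"""Typed exceptions.

Statistics that are mathematically undefined for the data at hand raise a
typed error rather than returning a silently wrong number; callers that can
tolerate a missing criterion (e.g. the Monte Carlo move loop) catch these
explicitly.
"""


class CwqsarError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CwqsarError):
    """Empty or structurally unusable input."""


class MalformedSmilesError(CwqsarError):
    """SMILES string violates the token grammar (unclosed bracket, bad %NN)."""


class ConfigurationError(CwqsarError):
    """Inconsistent or unsatisfiable configuration."""


class DegenerateDataError(CwqsarError):
    """Zero variance (or similar degeneracy) where a correlation is required."""


class UndefinedStatisticError(CwqsarError):
    """A criterion has no defined value for this data (e.g. no supporters)."""


class SplitError(CwqsarError):
    """A split assignment leaves a required subset empty or is malformed."""


class TaskMismatchError(CwqsarError):
    """A regression model asked to classify, or vice versa."""


class ModelStateError(CwqsarError):
    """Operation on an unfitted or inconsistent model."""


class ComparabilityError(CwqsarError):
    """Multi-run comparison across runs with incompatible configurations."""


class ParseError(CwqsarError):
    """Dataset file violates the expected tabular contract."""


class GenerationError(CwqsarError):
    """Synthetic-data configuration cannot be satisfied."""
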