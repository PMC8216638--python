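"""Exception hierarchy shared across the pipeline stages."""


class ArtselectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArtselectError):
    """Invalid cohort, labeling, or pipeline configuration."""


class SchemaError(ArtselectError):
    """Malformed tabular input (missing column, bad value, duplicate id)."""


class DegenerateInputError(ArtselectError):
    """Input that makes the requested computation ill-posed."""


class InsufficientDataError(ArtselectError):
    """Too few observations for the requested estimate."""


class UndefinedROCError(ArtselectError):
    """ROC requested when only one label class is present."""


class SelectionError(ArtselectError):
    """Greedy model selection left no surviving candidates."""


class RuleEvaluationError(ArtselectError):
    """A guideline rule references a predictor missing from the data."""


class ComparisonError(ArtselectError):
    """Mismatched subjects in a train-vs-validation comparison."""
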