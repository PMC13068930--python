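"""Exception types shared across the pipeline."""


class ExpobagError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExpobagError):
    """Invalid simulator or pipeline configuration."""


class SchemaError(ExpobagError):
    """A table is missing required columns or has mismatched features."""


class DegenerateModelError(ExpobagError):
    """A fit cannot proceed (constant target, near-zero bias slope, ...)."""


class ConditioningError(ExpobagError):
    """A design matrix is rank deficient or numerically singular."""


class ConsistencyError(ExpobagError):
    """An internal identity (e.g. Shapley local accuracy) was violated."""


class PipelineIntegrityError(ExpobagError):
    """A cross-stage contract was violated (e.g. overlapping participant sets)."""
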