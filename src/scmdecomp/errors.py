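"""Exception hierarchy shared across the pipeline stages."""


class ScmDecompError(Exception):
    """Base class for all package errors."""


class ConfigError(ScmDecompError):
    """Invalid configuration value (unknown mode, bad window, missing field)."""


class SchemaError(ScmDecompError):
    """Input table is missing a required column or has an invalid dtype."""


class DegenerateCellError(ScmDecompError):
    """A standardization cell has a zero or missing reference SD."""


class EmptyPoolError(ScmDecompError):
    """A pool rule left no eligible control districts."""


class MissingDataError(ScmDecompError):
    """Required panel rows (e.g. treated-unit pre/post observations) are absent."""


class SolverError(ScmDecompError):
    """The weight solver failed to converge; carries the solver status message."""


class RankError(ScmDecompError):
    """A regression design matrix is rank deficient."""


class ConsistencyError(ScmDecompError):
    """A subgroup panel violates an internal identity (proportions, aggregation)."""
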