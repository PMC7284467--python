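"""Exception hierarchy shared across the pipeline stages."""


class DietomicsError(Exception):
    """Base class for all package errors."""


class InputError(DietomicsError):
    """Invalid user-supplied data (values, rates, ranges)."""


class ConfigurationError(DietomicsError):
    """Invalid or inconsistent configuration (index specs, run config)."""


class SchemaError(DietomicsError):
    """A table is missing required columns."""


class DegenerateDataError(DietomicsError):
    """Data admit no meaningful answer (constant vector, zero variance)."""


class StratumError(DietomicsError):
    """A quantile stratum holds fewer observations than bins."""


class SingularDesignError(DietomicsError):
    """Rank-deficient regression design matrix."""


class PipelineError(DietomicsError):
    """Stage-level failure during orchestration."""
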