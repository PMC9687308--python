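"""Error classes shared across the package."""


class PolypillCEError(Exception):
    """Base class for all package errors."""


class SchemaError(PolypillCEError):
    """A parameter file is structurally wrong (missing/unknown keys, bad types)."""


class ValidationError(PolypillCEError, ValueError):
    """A parameter value violates a documented invariant."""


class ConfigurationError(PolypillCEError):
    """A cross-reference between model pieces cannot be resolved
    (e.g. a risk-equation covariate absent from the cohort profile)."""


class NumericError(PolypillCEError):
    """A non-finite or impossible quantity appeared during a model run."""
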