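"""Exception hierarchy shared across the package."""


class RegulaburdenError(Exception):
    """Base class for all package errors."""


class SchemaError(RegulaburdenError):
    """An input file does not match its documented column schema."""


class ValidationError(RegulaburdenError):
    """A value violates a domain invariant (bad position, negative count...)."""


class UnknownVariantError(RegulaburdenError, KeyError):
    """A variant id was requested that is not present in the catalog/table."""


class NormalizationError(RegulaburdenError):
    """A reporter plate cannot be normalized (e.g. no wild-type wells)."""


class InsufficientDataError(RegulaburdenError):
    """Too few replicates/observations for the requested statistic."""


class ConfigurationError(RegulaburdenError):
    """Inconsistent or incomplete analysis configuration."""


class DegeneratePredictorError(RegulaburdenError):
    """Regression predictor has zero variance."""


class UndefinedStatisticError(RegulaburdenError):
    """Requested statistic is undefined for the input (e.g. monomorphic locus)."""


class ConvergenceError(RegulaburdenError):
    """Iterative algorithm failed to converge within the iteration budget."""


class SamplingError(RegulaburdenError):
    """Requested cohort size exceeds the available phenotype tail."""


class IntegrityError(RegulaburdenError):
    """Bundled fixture digest mismatch."""
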