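"""Exception hierarchy shared by all pipeline stages."""


class MiracleError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MiracleError):
    """A file could not be parsed into the expected tabular/GMT structure."""


class SchemaError(MiracleError):
    """A table is missing required columns or has an invalid dtype."""


class ValidationError(MiracleError):
    """A value violates a domain-type invariant."""


class EmptyInputError(MiracleError):
    """An input collapsed to zero usable rows/columns after validation."""


class NoOverlapError(MiracleError):
    """A gene set shares no genes with the expression profile."""


class DegenerateDataError(MiracleError):
    """Data carry no usable signal (zero events, zero variance, ...)."""


class NonIdentifiableError(MiracleError):
    """A model parameter cannot be estimated (e.g. constant predictor)."""


class ConvergenceError(MiracleError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""


class StratificationError(MiracleError):
    """Cohort stratification could not be carried out."""


class ContractError(MiracleError):
    """An operation was called with arguments violating its contract."""


class LabellingError(MiracleError):
    """A clinical response code is outside the accepted vocabulary."""
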