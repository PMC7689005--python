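"""Exception hierarchy for mrkit.

All errors raised by the library derive from :class:`MrKitError` so callers
can catch them with a single except clause; subclasses distinguish
configuration mistakes (bad column maps, out-of-range parameters) from
data-level validation failures and from analysis preconditions.
"""


class MrKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrKitError):
    """A user-supplied setting is invalid (missing column, bad mode, ...)."""


class ValidationError(MrKitError):
    """A data row or object violates its invariants."""


class HarmonizationError(MrKitError):
    """Exposure and outcome tables cannot be harmonized."""


class InsufficientInstrumentsError(MrKitError):
    """Fewer instruments than the estimator requires."""


class SingularDesignError(MrKitError):
    """Regression design is degenerate (e.g. all exposure betas equal)."""


class PipelineError(MrKitError):
    """The end-to-end analysis cannot proceed; message carries stage counts."""
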