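"""Exception hierarchy for apoe4risk."""


class Apoe4RiskError(Exception):
    """Base class for all apoe4risk errors."""


class ConfigurationError(Apoe4RiskError, ValueError):
    """Invalid model constants (e.g. non-positive standard deviation)."""


class ValidationError(Apoe4RiskError, ValueError):
    """Invalid user-supplied data (distributions, pedigrees, documents)."""


class OnsetRangeError(ValidationError):
    """Age of onset outside the range the estimator accepts."""


class PedigreeStructureError(ValidationError):
    """Pedigree members attached to the wrong slot or malformed."""


class UnknownLevelError(Apoe4RiskError, LookupError):
    """Requested hazard-factor level does not exist."""
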