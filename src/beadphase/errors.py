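"""Exception types shared across the package."""


class BeadphaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BeadphaseError, ValueError):
    """A numeric parameter violates its contract (e.g. negative rate)."""


class InvalidInputError(BeadphaseError, ValueError):
    """Input data violates a precondition (e.g. unequal sequence lengths)."""


class ConfigurationError(BeadphaseError, ValueError):
    """A configuration is internally inconsistent (e.g. ambiguous tag set)."""


class UndefinedResultError(BeadphaseError):
    """The requested statistic is undefined on this input (e.g. no eligible
    clusters for a phasing rate); raised instead of silently returning 0."""
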