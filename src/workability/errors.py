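"""Exception hierarchy for the work-ability evaluation pipeline."""


class WorkabilityError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WorkabilityError):
    """Invalid expert-threshold configuration (schema or invariant violation)."""


class IntervalError(ConfigError):
    """Level intervals overlap, leave gaps, or fail to cover the value domain."""


class MissingFeatureError(WorkabilityError):
    """A record or table lacks one or more required feature columns."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing feature(s): {', '.join(self.missing)}")


class DomainError(WorkabilityError):
    """A raw value lies outside the admissible domain of its feature."""


class ParameterError(WorkabilityError):
    """Membership-function knots are unordered or otherwise invalid."""


class SampleSizeError(WorkabilityError):
    """Too few subjects for the requested operation (quartile split needs n >= 4)."""


class DegenerateLabelError(WorkabilityError):
    """Training labels contain fewer than two distinct classes."""


class UndefinedMetricError(WorkabilityError):
    """A classification metric is undefined (empty confusion matrix)."""
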