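"""Exception hierarchy for the modmod pipeline.

Exit-code mapping used by the CLI: validation/configuration problems map to
exit code 2, missing upstream artifacts to exit code 3.
"""


class ModmodError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ModmodError):
    """A generator / scenario / pipeline configuration violates its invariants."""


class ValidationError(ModmodError):
    """Input data violates a stated precondition (range, type, shape)."""


class DegenerateVariableError(ModmodError):
    """A variable has zero variance where nonzero variance is required."""


class UndefinedReliabilityError(DegenerateVariableError):
    """Reliability coefficient undefined because the total score does not vary."""


class CollinearityError(ModmodError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient in column(s): " + ", ".join(self.columns)
        )


class SpecificationError(ModmodError):
    """A model operation was called with arguments inconsistent with the model form."""


class GroupingError(ModmodError):
    """A grouped comparison is impossible (a group is absent or too small)."""


class DependencyError(ModmodError):
    """A pipeline stage requires an artifact that no earlier stage produced."""
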