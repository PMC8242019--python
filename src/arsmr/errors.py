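"""Exception hierarchy shared across the package."""


class ArsmrError(Exception):
    """Base class for all package errors."""


class FormatError(ArsmrError):
    """A delimited input file does not have the expected layout."""


class ValidationError(ArsmrError):
    """Input values violate a documented invariant."""


class HarmonizationError(ArsmrError):
    """Cohort allele coding cannot be reconciled with the instrument table."""


class DegenerateInputError(ArsmrError):
    """Input is structurally valid but statistically degenerate (e.g. zero variance)."""


class FeasibilityError(ArsmrError):
    """Requested simulation targets are jointly unattainable."""


class ConvergenceError(ArsmrError):
    """An iterative fit failed to converge within its budget."""


class StratumLookupError(ArsmrError):
    """A participant's stratum has no matching reference-model cell."""


class NumericalError(ArsmrError):
    """A matrix operation failed for numerical reasons (singularity etc.)."""
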