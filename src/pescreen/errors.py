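"""Exception hierarchy for the screening pipeline."""


class PescreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PescreenError):
    """A parameter file or spec is internally inconsistent or names an unknown key."""


class DomainError(PescreenError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class RangeError(DomainError):
    """A gestational age falls outside the validity range of a median model."""


class DegenerateInputError(DomainError):
    """Input has no variability (e.g. zero variance) where a statistic needs some."""


class PosteriorNumericalError(PescreenError):
    """The posterior normalizer underflowed: grid too narrow or MoMs too extreme."""
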