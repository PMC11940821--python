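"""Exception hierarchy shared across behavcal modules."""


class BehavcalError(Exception):
    """Base class for all behavcal errors."""


class FormatError(BehavcalError, ValueError):
    """A delimited input file does not match the expected layout."""


class ValidationError(BehavcalError, ValueError):
    """Input data violates a domain invariant (negative counts, overlaps...)."""


class ConfigurationError(BehavcalError, ValueError):
    """A configuration object is internally inconsistent."""


class DegenerateProblemError(BehavcalError, ValueError):
    """A binary classification problem has only one class present."""
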