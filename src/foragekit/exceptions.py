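"""Exception types raised across the package."""


class ForagekitError(Exception):
    """Base class for all package-specific errors."""


class UnknownConditionError(ForagekitError, ValueError):
    """Raised when a condition name is not one of the four task conditions."""


class MovementTimeFitError(ForagekitError, ValueError):
    """Raised when a radius tier lacks the data needed for a regression."""


class UnknownRadiusTierError(ForagekitError, KeyError):
    """Raised when a radius does not match any fitted tier."""


class NonpositiveTimeError(ForagekitError, ValueError):
    """Raised when a predicted movement time is not strictly positive."""


class NoCandidatesError(ForagekitError, ValueError):
    """Raised when a choice is requested but no legal targets remain."""


class LikelihoodError(ForagekitError, ValueError):
    """Raised when a scored choice cannot be assigned a probability."""


class FitError(ForagekitError, RuntimeError):
    """Raised when every optimizer restart fails."""


class DegenerateWeightsError(ForagekitError, ValueError):
    """Raised when look-ahead weights cannot be normalized."""


class SessionFormatError(ForagekitError, ValueError):
    """Raised on malformed or unit-inconsistent session files."""
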