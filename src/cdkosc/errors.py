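"""Exception hierarchy shared across the package."""


class CdkOscError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CdkOscError, ValueError):
    """A parameter or input lies outside its physical domain."""


class ResolutionError(CdkOscError, ValueError):
    """The requested step size cannot resolve the delay or rate scale."""


class NoFixedPointError(CdkOscError, ValueError):
    """The relay limit has no interior fixed point (c >= 1)."""


class NoOscillationError(CdkOscError, ValueError):
    """A closed-form oscillation was requested outside the oscillatory range."""


class InsufficientDataError(CdkOscError, ValueError):
    """A trajectory or curve is too short to analyze (distinct from 'not oscillating')."""


class FitError(CdkOscError, ValueError):
    """A response curve is degenerate and cannot be fitted."""


class ConfigError(CdkOscError, ValueError):
    """A structured configuration file is invalid."""
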