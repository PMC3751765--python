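"""Exception types shared across the package."""


class AhpError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AhpError):
    """Invalid hierarchy or simulation configuration."""


class SurveyError(AhpError):
    """Malformed or inconsistent survey data."""


class DesignError(AhpError):
    """A comparison design is incomplete or contradictory."""


class ComputationError(AhpError):
    """A numerical routine failed (e.g. power iteration did not converge)."""
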