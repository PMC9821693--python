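"""Exception types shared across the package."""


class WhiskerfitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WhiskerfitError):
    """An input file does not have the expected layout."""


class ConfigurationError(WhiskerfitError):
    """A parameter value is inconsistent or out of range."""


class DegenerateTraceError(WhiskerfitError):
    """A trace is too short or too malformed to process."""


class FitError(WhiskerfitError):
    """A model fit failed to converge from every start."""


class NotConformableError(WhiskerfitError):
    """A constant-curvature (A = 0) whisker cannot be placed on the Euler spiral."""
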