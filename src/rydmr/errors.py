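"""Exception hierarchy shared across the package."""


class RydmrError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RydmrError, ValueError):
    """A physical or model parameter is out of its valid domain."""


class SpinSpaceSizeError(RydmrError, ValueError):
    """The requested joint spin space exceeds the configured nuclear cap."""


class IntegrationError(RydmrError, RuntimeError):
    """Numerical propagation became unstable (e.g. trace growth)."""


class FitError(RydmrError, RuntimeError):
    """A least-squares fit failed to converge."""


class UnidentifiableParameterError(FitError):
    """The data do not constrain one or more fit parameters."""


class DataError(RydmrError, ValueError):
    """Malformed or inconsistent input data."""
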