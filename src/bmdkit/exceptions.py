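"""Exception hierarchy."""


class BmdError(Exception):
    """Base class for all package errors."""


class DataError(BmdError):
    """Invalid or inconsistent dose-response data."""


class InvalidModelError(BmdError):
    """Model specification or fitted-curve problem."""


class ConvergenceError(BmdError):
    """Estimation failed to converge or too many replicates failed."""


class NotReachableError(BmdError):
    """The benchmark response is outside the fitted curve's range."""


class FlatCurveError(BmdError):
    """Curve too flat at the benchmark dose for delta-method inference."""
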