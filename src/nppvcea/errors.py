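"""Exception hierarchy. All package errors derive from :class:`NppvCeaError`."""


class NppvCeaError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(NppvCeaError):
    """Invalid configuration value; the message names the offending field."""


class InfeasibleMomentsError(NppvCeaError):
    """Requested moments cannot be matched by the distribution family."""


class EstimationError(NppvCeaError):
    """A quantity cannot be estimated from the supplied trial data."""


class DataError(NppvCeaError):
    """Malformed or inconsistent input data."""


class ModelError(NppvCeaError):
    """Structurally invalid model input (e.g. transition rows not summing to 1)."""
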