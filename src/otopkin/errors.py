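"""Exception hierarchy shared across the package."""


class OtopkinError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OtopkinError, ValueError):
    """A numerical parameter violates its domain (e.g. non-positive rate)."""


class ModelError(OtopkinError, ValueError):
    """A channel-model definition is internally inconsistent."""


class ConfigurationError(OtopkinError, ValueError):
    """A run/protocol configuration is incomplete or contradictory."""


class DataError(OtopkinError, ValueError):
    """An input data table (trace, dose-response) cannot be used."""


class FitError(OtopkinError, RuntimeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""
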