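"""Shared exception types, mapped to CLI exit codes (config=2, solver=3, data=4)."""


class ConfigurationError(ValueError):
    """Invalid or incomplete run configuration / model setup."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class InfeasibleModelError(RuntimeError):
    """A model instance admits no feasible flux distribution."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
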