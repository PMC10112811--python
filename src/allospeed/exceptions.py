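"""Exception and warning types used across the package."""


class ConfigurationError(ValueError):
    """A model specification, parameter set, or config is internally inconsistent."""


class SchemaError(ValueError):
    """A dataset file does not provide the mandatory columns."""


class ValidationError(ValueError):
    """One or more dataset rows failed validation; carries row-numbered diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        msg = "; ".join(f"row {row}: {reason}" for row, reason in self.diagnostics)
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {msg}")


class DegenerateDrawsError(ValueError):
    """Posterior draws have zero variance, so importance weights are undefined."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics (r-hat / effective sample size) missed their thresholds."""
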