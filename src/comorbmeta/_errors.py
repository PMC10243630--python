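"""Exception hierarchy shared across the pipeline stages."""


class ComorbmetaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ComorbmetaError):
    """Invalid user-supplied configuration (profiles, registries, run configs)."""


class ValidationError(ComorbmetaError):
    """Invalid data values passed to a computation (e.g. non-positive creatinine)."""


class FitError(ComorbmetaError):
    """A model fit failed (rank deficiency, separation, non-convergence)."""


class ConvergenceError(FitError):
    """An MCMC fit did not meet the configured convergence gate."""
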