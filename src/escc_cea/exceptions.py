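"""Exception hierarchy for the package."""


class EsccCeaError(Exception):
    """Base class for all package errors."""


class ValidationError(EsccCeaError, ValueError):
    """An input violated a documented precondition or invariant."""


class ConfigError(ValidationError):
    """A configuration file failed schema validation; message carries the field path."""


class FittingError(EsccCeaError, RuntimeError):
    """Maximum-likelihood fitting could not proceed (e.g. all observations censored)."""


class InfeasibleReconstructionError(ValidationError):
    """Pseudo-IPD reconstruction cannot honour the requested sample size."""
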