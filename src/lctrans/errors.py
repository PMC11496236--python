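"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Input data or configuration violates a documented contract."""


class NonEstimableError(RuntimeError):
    """A requested parameter cannot be estimated from the data provided."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed in a way that cannot be returned as a flagged fit."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at its iteration cap before meeting tolerance."""
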