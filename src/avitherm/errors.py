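"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class NumericalFailureError(RuntimeError):
    """An iterative solve failed to converge; carries diagnostic context."""


class NoBreakpointError(RuntimeError):
    """A metabolic-rate curve has no detectable lower critical temperature."""
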