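"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when user-supplied configuration or data violates a contract."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to produce any usable solution."""
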