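"""Exception types shared across the package."""


class InvarscopeError(Exception):
    """Base class for package-specific failures."""


class InvalidArgumentError(InvarscopeError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedValueError(InvarscopeError, ValueError):
    """A quantity (similarity, accuracy) is mathematically undefined here."""


class UnavailableResourceError(InvarscopeError, RuntimeError):
    """An external resource (weights file, dataset) could not be loaded."""


class TrainingFailureError(InvarscopeError, RuntimeError):
    """Model training diverged or produced non-finite parameters."""
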