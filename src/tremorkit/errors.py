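"""Exception taxonomy shared across the package."""


class TremorkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TremorkitError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file does not conform to the documented on-disk dialect."""


class UnsupportedOperation(TremorkitError):
    """A structurally valid request outside the supported envelope
    (e.g. downsampling through :func:`resample`)."""


class DegenerateModelError(ValidationError):
    """A classifier cannot be trained (e.g. a single-class label vector)."""
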