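"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`TexturalityError`
so callers (and the CLI) can catch one base class.  ``code`` is a stable,
machine-readable identifier used by the CLI for exit diagnostics.
"""


class TexturalityError(Exception):
    """Base class for all package-specific errors."""

    code = "error"


class ValidationError(TexturalityError, ValueError):
    """A value violates an operation's precondition."""

    code = "invalid-value"


class SizeError(ValidationError):
    """An image or array has an unsupported size (divisibility, squareness)."""

    code = "bad-size"


class ShapeError(ValidationError):
    """Array shapes disagree with the configuration they claim to follow."""

    code = "shape-mismatch"


class UnsupportedConfigError(ValidationError):
    """The requested operation is only defined for the default 4x4 layout."""

    code = "unsupported-config"


class ConvergenceError(TexturalityError, RuntimeError):
    """An iterative fit failed to converge."""

    code = "no-convergence"


class ImageReadError(TexturalityError, IOError):
    """A raster file could not be read."""

    code = "unreadable-image"


class RatingsFormatError(ValidationError):
    """A behavioral-ratings table violates the expected CSV dialect."""

    code = "bad-ratings"
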