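"""Exception hierarchy for evsig.

All validation failures raise :class:`ValidationError` (a ``ValueError``),
so callers that do not care about the finer distinction can catch one type.
"""


class EvsigError(Exception):
    """Base class for all evsig errors."""


class ValidationError(EvsigError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(EvsigError, ValueError):
    """A file could not be parsed as the expected dialect."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (e.g. an all-zero curve)."""


class LeakageError(EvsigError, RuntimeError):
    """Synthetic (oversampled) rows, or their parents, reached a validation
    or test partition.  This is an enforced contract of the pipeline, never
    a warning."""
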