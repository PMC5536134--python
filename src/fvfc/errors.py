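"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`FvfcError`
so callers (and the CLI) can distinguish input problems from bugs.
"""


class FvfcError(Exception):
    """Base class for all fvfc errors."""


class MalformedHeaderError(FvfcError):
    """Dense expression file header is missing, empty, or has blank IDs."""


class DuplicateIDError(FvfcError):
    """Gene or cell identifiers are not unique."""


class DimensionMismatchError(FvfcError):
    """Matrix dimensions disagree with sidecar ID files or companion objects."""


class AnnotationConflictError(FvfcError):
    """A cell ID appears more than once with conflicting labels."""


class EmptyResultError(FvfcError):
    """A filtering step removed everything."""


class ConstantGeneError(FvfcError):
    """A gene has zero variance where nonzero variance is required."""


class ZeroVarianceError(FvfcError):
    """A vector has zero variance where nonzero variance is required."""


class DegenerateInputError(FvfcError):
    """Input is degenerate for the requested computation (e.g. a point set
    collapsed to a single location, or an all-zero module submatrix)."""


class UnknownModuleError(FvfcError):
    """A module ID does not exist in the eigengene set."""


class StageError(FvfcError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
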