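"""Exception hierarchy shared across the package."""


class CredmetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CredmetaError, ValueError):
    """A study table is missing required columns."""


class RecordValidationError(CredmetaError, ValueError):
    """A study record violates a field constraint (names row and field)."""


class DegenerateInputError(CredmetaError, ValueError):
    """Input is structurally valid but statistically unusable (e.g. empty arm)."""


class InsufficientStudiesError(CredmetaError, ValueError):
    """Fewer studies than the operation's minimum k."""


class IneligibleAssociationError(InsufficientStudiesError):
    """An association has fewer than the minimum independent datasets."""

    def __init__(self, key, k: int, minimum: int = 3):
        self.key = key
        self.k = k
        self.minimum = minimum
        super().__init__(
            f"association {key} has {k} analyzable studies; {minimum} required"
        )


class NotGradeableError(CredmetaError, ValueError):
    """Credibility grading requested for a non-significant pooled result."""
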