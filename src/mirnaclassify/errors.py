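"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`MiRNAClassifyError`
so callers (and the CLI exit-code mapping) can catch package failures
without masking programming errors.
"""


class MiRNAClassifyError(Exception):
    """Base class for all package errors."""


class InvalidAlphabetError(MiRNAClassifyError):
    """Sequence contains characters outside {A,C,G,U} after normalization."""


class TooShortError(MiRNAClassifyError):
    """Sequence shorter than the minimum required for the operation."""


class FoldMismatchError(MiRNAClassifyError):
    """Dot-bracket structure length disagrees with the sequence length."""


class MalformedStructureError(MiRNAClassifyError):
    """Dot-bracket string has unbalanced brackets or illegal characters."""


class IncompleteFoldError(MiRNAClassifyError):
    """A thermodynamic scalar needed by a feature is missing from the fold."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"fold is missing thermodynamic field {field!r}")


class FoldingBackendError(MiRNAClassifyError):
    """The external RNA folding backend is unavailable or failed."""


class DimensionError(MiRNAClassifyError):
    """Vector/matrix dimensions do not agree."""


class UndefinedDistanceError(MiRNAClassifyError):
    """Rogers-Tanimoto denominator is zero (both vectors all-zero)."""


class InfeasibleSelectionError(MiRNAClassifyError):
    """A resampling request cannot be satisfied (k too large, no weight)."""


class LabelError(MiRNAClassifyError):
    """Labels are not binary or a required class is absent."""


class BalanceContractError(MiRNAClassifyError):
    """A base learner received an unbalanced training set."""


class UndefinedMetricError(MiRNAClassifyError):
    """A confusion-matrix metric is undefined (empty class)."""


class SpecError(MiRNAClassifyError):
    """A synthetic-data specification is invalid."""


class ParseError(MiRNAClassifyError):
    """An input file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateIdError(ParseError):
    """Two records in one file share an id."""
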