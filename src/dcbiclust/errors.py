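"""Exception hierarchy for dcbiclust.

All library errors derive from :class:`DcbiclustError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class DcbiclustError(Exception):
    """Base class for all dcbiclust errors."""


class IdentifierError(DcbiclustError, KeyError):
    """A gene or condition id referenced by a bicluster is absent from the matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return Exception.__str__(self)


class DataError(DcbiclustError, ValueError):
    """Input values are malformed (non-finite entries, ragged rows, duplicates)."""


class ParameterError(DcbiclustError, ValueError):
    """A tuning parameter is outside its legal range (a <= 0, phi <= 0, ...)."""


class DegenerateFitError(DcbiclustError, ValueError):
    """A two-way fit was requested on a submatrix with I < 2 or J < 2."""


class NotScorableError(DcbiclustError, ValueError):
    """A bicluster cannot receive a differential co-expression score.

    Raised when the complement group G2 has fewer than 2 conditions: the
    co-expression of the gene set is then a global effect and cannot be
    tested against non-bicluster conditions.
    """


class LayoutError(DcbiclustError, ValueError):
    """Synthetic implant blocks overlap or do not fit inside the matrix."""
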