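"""Exception types shared across the package.

Builtin ``NameError``, ``IndexError`` and ``FileExistsError`` are used
directly where they fit (unknown column, out-of-range slice position,
refusing to overwrite a directory).
"""


class TidyCellsError(Exception):
    """Base class for all package-specific errors."""


class IdentifierError(TidyCellsError):
    """Duplicate or unknown cell/feature identifier."""


class ShapeError(TidyCellsError):
    """Dimension mismatch between matrices, id lists or metadata."""


class DuplicationError(TidyCellsError):
    """Cell duplication requested at the container level, where it is forbidden."""


class ReservedColumnError(TidyCellsError):
    """Attempt to write a protected column (the key column or a reduction label)."""


class NameCollisionError(TidyCellsError):
    """A new column or label collides with an existing one."""


class ReadOnlyColumnError(TidyCellsError):
    """Attempt to modify a view-only (reduction-backed) or key column."""


class SampleSizeError(TidyCellsError):
    """Requested sample size exceeds group size without replacement."""


class AggregationError(TidyCellsError):
    """A summarise aggregation did not reduce its group to a scalar."""


class JoinKeyError(TidyCellsError):
    """Join requested with an empty key column set."""


class PatternError(TidyCellsError):
    """Regex for extract has no capture groups or the wrong number of them."""


class FeatureNotFoundError(TidyCellsError):
    """Requested feature ids absent from the assay."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"features not found: {', '.join(map(str, self.missing))}")


class GroupKeyError(TidyCellsError):
    """Nest/group requested with an empty key column set."""


class FormatError(TidyCellsError):
    """Malformed on-disk file (MatrixMarket triplets, TSV/CSV tables)."""


class PolygonError(TidyCellsError):
    """Degenerate polygon (fewer than 3 vertices or zero area)."""


class EmptyInputError(TidyCellsError):
    """Empty array where at least one value is required."""


class ParamError(TidyCellsError):
    """Invalid parameter combination (simulation simplex, sampling args, ...)."""
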