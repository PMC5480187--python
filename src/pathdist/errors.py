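"""Exception hierarchy shared across the package."""

from __future__ import annotations

import numpy as np


class PathdistError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdentifierError(PathdistError):
    """A gene id, sample id, or gene-set name occurs more than once."""


class MatrixParseError(PathdistError):
    """A text matrix or GMT file could not be parsed."""


class ShapeError(PathdistError):
    """An input has an unusable shape (e.g. fewer than 2 samples)."""


class DataError(PathdistError):
    """Input values are unusable (non-finite, non-numeric)."""


class ParameterError(PathdistError):
    """An option value is outside its valid range."""


class ConfigurationError(PathdistError):
    """A configuration leaves nothing to compute (e.g. no pathway matched)."""


class AlignmentError(PathdistError):
    """Two objects that must share a sample set do not."""


class DegenerateScoreError(PathdistError):
    """Every pathway produced a single cluster, so all pairwise scores are 0.

    With no multi-cluster pathway the voting denominator is empty and the
    disagreement proportion is 0 for every sample pair; clustering such a
    matrix is meaningless.  The all-zero matrix is attached for callers that
    want to inspect or export it anyway.
    """

    def __init__(self, message: str, zero_matrix: np.ndarray | None = None):
        super().__init__(message)
        self.zero_matrix = zero_matrix
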