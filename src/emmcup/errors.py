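"""Exception hierarchy."""


class EmmcupError(Exception):
    """Base class for package errors."""


class RankDeficiencyError(EmmcupError):
    """Basis Gram matrix is singular or the mask cannot support the basis."""


class DegenerateInputError(EmmcupError):
    """Input lacks the structure an operation requires (e.g. too few levels)."""


class NumericalFailureError(EmmcupError):
    """Solver produced a non-finite quantity."""


class UndefinedMetricError(EmmcupError):
    """A metric's denominator vanished."""


class FormatError(EmmcupError):
    """A file could not be read or written in a supported image format."""
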