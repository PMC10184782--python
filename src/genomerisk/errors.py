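"""Exception types shared across the package."""


class GenomeRiskError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GenomeRiskError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive rate)."""


class MalformedInputError(GenomeRiskError, ValueError):
    """An input file or text blob does not conform to its declared format."""


class InsufficientDataError(GenomeRiskError, ValueError):
    """Too few observations to carry out the requested estimation."""


class EmptySupportError(GenomeRiskError, ValueError):
    """The requested summary has no data in its support (e.g. no epochs
    older than the age cutoff, no scored substitutions)."""


class UndefinedMomentError(GenomeRiskError, ValueError):
    """A moment-based statistic is undefined (e.g. zero variance)."""


class RankDeficiencyError(GenomeRiskError, ValueError):
    """The design matrix is rank deficient after the requested transform."""
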