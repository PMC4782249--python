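"""Exception hierarchy for morphnet.

All domain errors derive from :class:`MorphnetError` so callers can catch
one base class at pipeline boundaries.
"""


class MorphnetError(Exception):
    """Base class for all morphnet domain errors."""


class FormatError(MorphnetError):
    """Malformed on-disk input (wrong dimensionality, non-integer atlas,
    missing region-table rows, ...)."""


class AlignmentError(MorphnetError):
    """Two volumes that must share voxel geometry do not."""


class GridAlignmentError(MorphnetError):
    """Two discretized distributions are not defined on the same grid."""


class DegenerateRegionError(MorphnetError):
    """A region has too few usable voxels for density estimation."""


class DegenerateDistributionError(MorphnetError):
    """Sample values have (numerically) zero spread; no density estimate
    is meaningful."""


class SizingError(MorphnetError):
    """Requested synthetic geometry cannot host the requested parcels."""


class UndefinedICCError(MorphnetError):
    """Total variance is zero; the intraclass correlation is undefined."""


class UndefinedCorrelationError(MorphnetError):
    """One of the vectors has zero variance; Pearson r is undefined."""


class UndefinedRatioError(MorphnetError):
    """A null-model mean is zero; the normalized metric is undefined."""
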