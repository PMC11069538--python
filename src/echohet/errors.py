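"""Exception hierarchy for echohet."""


class EchoHetError(Exception):
    """Base class for all echohet errors."""


class FormatError(EchoHetError):
    """An input file could not be parsed in any supported format."""


class UnsupportedContentError(EchoHetError):
    """A file parsed but holds content outside the tool's scope
    (e.g. multi-frame cine DICOM)."""


class ROIValidationError(EchoHetError):
    """An ROI polygon violates its contract (too few vertices,
    self-intersection, out-of-bounds vertex)."""


class DegenerateROIError(EchoHetError):
    """An ROI rasterizes to fewer than two pixels (or has zero area),
    so no dispersion statistic is defined on it."""


class UndefinedScoreError(EchoHetError):
    """The heterogeneity score is undefined (all-black ROI: mean
    intensity is zero, the CV denominator)."""


class CohortError(EchoHetError):
    """A cohort-level statistical routine received degenerate input
    (single class, constant grades, missing groups, ...)."""
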