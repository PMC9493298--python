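"""Exception hierarchy shared by all pipeline stages."""


class PetHeteroError(Exception):
    """Base class for all package errors."""


class EmptyVoiError(PetHeteroError):
    """No voxel in the bounding box reaches the segmentation threshold."""


class InvalidBoxError(PetHeteroError):
    """Bounding box is degenerate or exceeds the volume extent."""


class ZeroMeanError(PetHeteroError):
    """Coefficient of variation is undefined because SUVmean is zero."""


class DegenerateRegressionError(PetHeteroError):
    """Threshold ladder has fewer than two distinct abscissa values."""


class SpecError(PetHeteroError):
    """A phantom or cohort specification violates its invariants."""


class OutOfRangeError(PetHeteroError):
    """Analytic oracle queried outside its domain of validity."""


class OrderError(PetHeteroError):
    """Quantiles supplied out of order (need q1 < median < q3)."""


class NoConvergenceError(PetHeteroError):
    """Iterative calibration failed to bracket or converge."""


class ConvergenceFailureError(PetHeteroError):
    """Model fit did not converge (e.g. monotone partial likelihood)."""


class NoEventsError(PetHeteroError):
    """Survival procedure requires at least one observed event."""


class EmptyInputError(PetHeteroError):
    """Estimator called on an empty sample."""


class OneClassError(PetHeteroError):
    """ROC analysis requires both outcome classes to be present."""


class DegenerateTableError(PetHeteroError):
    """Contingency table has an empty row or column."""
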