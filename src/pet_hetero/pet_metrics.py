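"""Semiquantitative FDG-PET tumor metrics from SUV volumes.

Implements the nine per-patient quantities used in intratumor metabolic
heterogeneity studies: SUVmax; metabolic tumor volume (MTV) and total lesion
glycolysis (TLG) at a fixed SUV 2.5 threshold and at 40% of SUVmax; the
coefficient of variation (CV) inside each of those volumes of interest; and
two heterogeneity indices defined as the negated slope of the linear
regression of MTV against a ladder of segmentation thresholds:

* HI-1 — fixed SUV thresholds 2.5, 3.0, 3.5 (units: mL per SUV unit);
* HI-2 — relative thresholds 30%..70% of SUVmax in 10-point steps
  (units: mL per percentage point of SUVmax).

Segmentation is deterministic: inside a user-supplied bounding box, the
closed superlevel set {SUV >= t} is reduced to the 26-connected component
containing the box's maximum-SUV voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateRegressionError,
    EmptyVoiError,
    InvalidBoxError,
    ZeroMeanError,
)

logger = logging.getLogger(__name__)

HI1_THRESHOLDS = (2.5, 3.0, 3.5)
HI2_FRACTIONS = (0.30, 0.40, 0.50, 0.60, 0.70)


@dataclass(frozen=True)
class SuvVolume:
    """A 3-D grid of SUV values with voxel spacing in mm.

    SUV is the body-weight-normalized standardized uptake value and is
    treated as dimensionless (g/mL convention). ``spacing`` is (dx, dy, dz)
    in mm; ``origin`` is the physical position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("SUV volume must be a 3-D array with nonempty axes")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be three positive lengths (mm)")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("SUV values must be finite and non-negative")

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class BoundingBox:
    """Voxel-index box: inclusive lower, exclusive upper, per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise InvalidBoxError("bounding box needs three axes")
        if any(lo >= hi for lo, hi in zip(self.lower, self.upper)):
            raise InvalidBoxError("bounding box must satisfy lower < upper per axis")
        if any(lo < 0 for lo in self.lower):
            raise InvalidBoxError("bounding box lower corner must be non-negative")

    def validate_against(self, volume: SuvVolume) -> None:
        if any(hi > n for hi, n in zip(self.upper, volume.values.shape)):
            raise InvalidBoxError(
                f"bounding box {self.upper} exceeds volume extent {volume.values.shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    @classmethod
    def whole(cls, volume: SuvVolume) -> "BoundingBox":
        return cls((0, 0, 0), tuple(volume.values.shape))


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation threshold: absolute SUV, or a fraction of box SUVmax."""

    kind: str  # "absolute_suv" | "fraction_of_max"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_suv", "fraction_of_max"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "absolute_suv" and self.value <= 0:
            raise ValueError("absolute SUV threshold must be > 0")
        if self.kind == "fraction_of_max" and not 0 < self.value <= 1:
            raise ValueError("fractional threshold must lie in (0, 1]")


@dataclass(frozen=True)
class Voi:
    """Boolean tumor mask congruent with its source volume."""

    mask: np.ndarray
    threshold_used: ThresholdSpec  # resolved to absolute SUV

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class SuvStats:
    suv_max: float
    suv_mean: float
    suv_sd: float  # sample SD, n-1 denominator
    n_voxels: int


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary-least-squares fit of MTV against threshold."""

    slope: float
    intercept: float
    x_values: tuple[float, ...]
    y_values: tuple[float, ...]


@dataclass(frozen=True)
class TumorParameters:
    """The nine per-patient PET quantities.

    Fields that are undefined for a given tumor (e.g. HI-1 when
    SUVmax <= 3.5) are reported as NaN, never silently zeroed.
    """

    suv_max: float
    mtv_2_5: float  # mL
    mtv_40: float  # mL
    tlg_2_5: float  # g
    tlg_40: float  # g
    cv_2_5: float
    cv_40: float
    hi_1: float  # mL per SUV unit
    hi_2: float  # mL per percentage point of SUVmax
    hi_1_fit: SlopeFit | None = field(default=None, compare=False, repr=False)
    hi_2_fit: SlopeFit | None = field(default=None, compare=False, repr=False)

    CSV_COLUMNS = (
        "suv_max",
        "mtv_2_5_ml",
        "mtv_40_ml",
        "tlg_2_5_g",
        "tlg_40_g",
        "cv_2_5",
        "cv_40",
        "hi_1",
        "hi_2",
    )

    def as_row(self) -> dict[str, float]:
        return {
            "suv_max": self.suv_max,
            "mtv_2_5_ml": self.mtv_2_5,
            "mtv_40_ml": self.mtv_40,
            "tlg_2_5_g": self.tlg_2_5,
            "tlg_40_g": self.tlg_40,
            "cv_2_5": self.cv_2_5,
            "cv_40": self.cv_40,
            "hi_1": self.hi_1,
            "hi_2": self.hi_2,
        }


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def segment_fixed(
    volume: SuvVolume, box: BoundingBox, t: float, connectivity: int = 26
) -> Voi:
    """Threshold segmentation at an absolute SUV ``t``.

    Returns the connected component of {SUV >= t} inside ``box`` that
    contains the box's maximum-SUV voxel. Voxels outside the box are never
    included.
    """
    if t <= 0:
        raise ValueError("absolute SUV threshold must be > 0")
    box.validate_against(volume)
    crop = volume.values[box.slices]
    supra = crop >= t
    if not supra.any():
        raise EmptyVoiError(
            f"no voxel in box reaches SUV {t} (box SUVmax = {crop.max():.3g})"
        )
    labels, _ = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    seed = np.unravel_index(np.argmax(crop), crop.shape)
    component = labels == labels[seed]
    mask = np.zeros(volume.values.shape, dtype=bool)
    mask[box.slices] = component
    return Voi(mask=mask, threshold_used=ThresholdSpec("absolute_suv", float(t)))


def segment_fraction(
    volume: SuvVolume, box: BoundingBox, f: float, connectivity: int = 26
) -> Voi:
    """Threshold segmentation at ``f`` x (maximum SUV inside the box)."""
    if not 0 < f <= 1:
        raise ValueError("fractional threshold must lie in (0, 1]")
    box.validate_against(volume)
    box_max = float(volume.values[box.slices].max())
    if box_max <= 0:
        raise EmptyVoiError("box contains no positive uptake")
    return segment_fixed(volume, box, f * box_max, connectivity=connectivity)


def suv_stats(volume: SuvVolume, voi: Voi) -> SuvStats:
    """SUVmax / SUVmean / sample SD over the VOI voxels."""
    if voi.mask.shape != volume.values.shape:
        raise ValueError("VOI mask not congruent with volume")
    vals = volume.values[voi.mask]
    if vals.size == 0:
        raise EmptyVoiError("VOI is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SuvStats(
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        suv_sd=sd,
        n_voxels=int(vals.size),
    )


def mtv(voi: Voi, spacing: tuple[float, float, float]) -> float:
    """Metabolic tumor volume in mL: voxel count x voxel volume (mm^3/1000)."""
    dx, dy, dz = spacing
    return voi.n_voxels * dx * dy * dz / 1000.0


def tlg(mtv_ml: float, suv_mean: float) -> float:
    """Total lesion glycolysis in g: MTV (mL) x SUVmean."""
    if mtv_ml < 0 or suv_mean < 0:
        raise ValueError("MTV and SUVmean must be non-negative")
    return mtv_ml * suv_mean


def cv(volume: SuvVolume, voi: Voi) -> float:
    """Coefficient of variation: SUV sample SD / SUVmean inside the VOI."""
    stats = suv_stats(volume, voi)
    if stats.suv_mean == 0:
        raise ZeroMeanError("CV undefined: SUVmean is zero")
    return stats.suv_sd / stats.suv_mean


def mtv_threshold_curve(
    volume: SuvVolume,
    box: BoundingBox,
    thresholds: list[ThresholdSpec],
    connectivity: int = 26,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """MTV as a function of threshold, the input to a heterogeneity index.

    Fixed thresholds put absolute SUV on the abscissa; fractional thresholds
    put percentage points of SUVmax (30, 40, ...) there. MTV is non-increasing
    along the ladder because superlevel sets are nested.
    """
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds")
    kinds = {spec.kind for spec in thresholds}
    if len(kinds) > 1:
        raise ValueError("all thresholds on one ladder must share a kind")
    kind = kinds.pop()
    xs, ys = [], []
    for spec in thresholds:
        if kind == "absolute_suv":
            voi = segment_fixed(volume, box, spec.value, connectivity=connectivity)
            xs.append(float(spec.value))
        else:
            voi = segment_fraction(volume, box, spec.value, connectivity=connectivity)
            xs.append(100.0 * spec.value)
        ys.append(mtv(voi, volume.spacing))
    return tuple(xs), tuple(ys)


def heterogeneity_index(
    x_values: tuple[float, ...] | list[float],
    y_values: tuple[float, ...] | list[float],
) -> tuple[float, SlopeFit]:
    """Negated OLS slope of MTV against threshold.

    A steeper decay of MTV with threshold means more heterogeneous uptake,
    so the index is non-negative whenever MTV is non-increasing.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateRegressionError("need >= 2 distinct threshold values")
    # centered normal equations; exactly zero slope for a flat MTV curve
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(xc @ yc) / float(xc @ xc)
    intercept = float(y.mean()) - slope * float(x.mean())
    fit = SlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        x_values=tuple(x.tolist()),
        y_values=tuple(y.tolist()),
    )
    return -fit.slope, fit


def compute_all_parameters(
    volume: SuvVolume, box: BoundingBox, connectivity: int = 26
) -> TumorParameters:
    """Assemble the full nine-parameter set for one tumor.

    Fixed-threshold quantities (MTV2.5 family, HI-1) are undefined when the
    tumor's SUVmax does not clear the respective thresholds; those fields are
    returned as NaN with a logged warning rather than truncated or zeroed.
    """
    box.validate_against(volume)
    suv_max = float(volume.values[box.slices].max())
    nan = float("nan")

    mtv_2_5 = tlg_2_5 = cv_2_5 = nan
    try:
        voi25 = segment_fixed(volume, box, 2.5, connectivity=connectivity)
        stats25 = suv_stats(volume, voi25)
        mtv_2_5 = mtv(voi25, volume.spacing)
        tlg_2_5 = tlg(mtv_2_5, stats25.suv_mean)
        cv_2_5 = stats25.suv_sd / stats25.suv_mean
    except EmptyVoiError:
        logger.warning(
            "MISSING_PARAMETER field=mtv_2_5 reason=suv_max_below_threshold suv_max=%.3f",
            suv_max,
        )

    voi40 = segment_fraction(volume, box, 0.40, connectivity=connectivity)
    stats40 = suv_stats(volume, voi40)
    mtv_40 = mtv(voi40, volume.spacing)
    tlg_40 = tlg(mtv_40, stats40.suv_mean)
    cv_40 = stats40.suv_sd / stats40.suv_mean

    hi_1, hi_1_fit = nan, None
    if suv_max > max(HI1_THRESHOLDS):
        xs, ys = mtv_threshold_curve(
            volume,
            box,
            [ThresholdSpec("absolute_suv", t) for t in HI1_THRESHOLDS],
            connectivity=connectivity,
        )
        hi_1, hi_1_fit = heterogeneity_index(xs, ys)
    else:
        logger.warning(
            "MISSING_PARAMETER field=hi_1 reason=suv_max_below_ladder suv_max=%.3f",
            suv_max,
        )

    xs2, ys2 = mtv_threshold_curve(
        volume,
        box,
        [ThresholdSpec("fraction_of_max", f) for f in HI2_FRACTIONS],
        connectivity=connectivity,
    )
    hi_2, hi_2_fit = heterogeneity_index(xs2, ys2)

    return TumorParameters(
        suv_max=suv_max,
        mtv_2_5=mtv_2_5,
        mtv_40=mtv_40,
        tlg_2_5=tlg_2_5,
        tlg_40=tlg_40,
        cv_2_5=cv_2_5,
        cv_40=cv_40,
        hi_1=hi_1,
        hi_2=hi_2,
        hi_1_fit=hi_1_fit,
        hi_2_fit=hi_2_fit,
    )
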