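"""Digital sphere phantoms with closed-form MTV(threshold) curves.

Radial uptake profiles on spherical tumors keep every downstream quantity
analytic: the superlevel set {SUV >= t} of a monotone radial profile is a
sphere (or spherical shell), so MTV, its regression slope against a
threshold ladder, and hence the heterogeneity indices all have closed forms.
Optional Gaussian PSF blur and additive Gaussian noise (clipped at zero)
reproduce the partial-volume phenomenology that makes measured uptake
distributions look more heterogeneous than the underlying tracer field.

Profiles
--------
uniform        SUV(r) = s_peak for r < radius
linear_decay   SUV(r) = s_peak * (1 - r/radius)
necrotic_core  SUV(r) = core_suv for r < core_radius, else s_peak
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import OutOfRangeError, SpecError
from .pet_metrics import SuvVolume, heterogeneity_index

PROFILES = ("uniform", "linear_decay", "necrotic_core")
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric ground-truth description of one spherical tumor."""

    radius_mm: float
    profile: str = "uniform"
    s_peak: float = 10.0
    background_suv: float = 0.5
    core_radius_mm: float | None = None
    core_suv: float | None = None
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    extent_mm: tuple[float, float, float] = (60.0, 60.0, 60.0)
    psf_fwhm_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.shape != "sphere":
            raise SpecError("only spherical phantoms are supported")
        if self.profile not in PROFILES:
            raise SpecError(f"unknown profile {self.profile!r}")
        if self.radius_mm <= 0:
            raise SpecError("radius_mm must be > 0")
        if not self.s_peak > self.background_suv >= 0:
            raise SpecError("need s_peak > background_suv >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise SpecError("spacing must be positive")
        if self.profile == "necrotic_core":
            if self.core_radius_mm is None or self.core_suv is None:
                raise SpecError("necrotic_core requires core_radius_mm and core_suv")
            if not 0 < self.core_radius_mm < self.radius_mm:
                raise SpecError("core_radius_mm must lie in (0, radius_mm)")
            if not 0 <= self.core_suv < self.s_peak:
                raise SpecError("core_suv must lie in [0, s_peak)")
        margin = [
            ext / 2 - self.radius_mm - 2 * sp
            for ext, sp in zip(self.extent_mm, self.spacing_mm)
        ]
        if min(margin) < 0:
            raise SpecError("extent must contain the sphere with >= 2-voxel margin")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise SpecError("psf_fwhm_mm and noise_sd must be >= 0")


def _profile_suv(spec: PhantomSpec, r: np.ndarray) -> np.ndarray:
    """Ideal SUV field as a function of radial distance (mm)."""
    inside = r < spec.radius_mm
    out = np.full(r.shape, spec.background_suv, dtype=float)
    if spec.profile == "uniform":
        out[inside] = spec.s_peak
    elif spec.profile == "linear_decay":
        out[inside] = spec.s_peak * (1.0 - r[inside] / spec.radius_mm)
    else:  # necrotic_core
        out[inside] = spec.s_peak
        out[r < spec.core_radius_mm] = spec.core_suv
    return out


def make_phantom(spec: PhantomSpec) -> SuvVolume:
    """Rasterize the spec onto a voxel grid; deterministic for a fixed spec.

    Each voxel is sampled at its center. Blur (if any) is an isotropic
    Gaussian of the stated FWHM applied in mm space; noise (if any) is
    additive Gaussian, seeded, and clipped at zero.
    """
    shape = tuple(
        int(round(ext / sp)) for ext, sp in zip(spec.extent_mm, spec.spacing_mm)
    )
    center = tuple(ext / 2.0 for ext in spec.extent_mm)
    axes = [
        (np.arange(n) + 0.5) * sp - c
        for n, sp, c in zip(shape, spec.spacing_mm, center)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    values = _profile_suv(spec, r)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * _FWHM_TO_SIGMA / sp for sp in spec.spacing_mm
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return SuvVolume(values=values, spacing=spec.spacing_mm)


def _sphere_ml(radius_mm: float) -> float:
    return (4.0 / 3.0) * math.pi * radius_mm**3 / 1000.0


def analytic_mtv(spec: PhantomSpec, t: float) -> float:
    """Closed-form MTV (mL) of the ideal, blur- and noise-free field.

    Returns 0 for thresholds above the profile peak; thresholds at or below
    the background are rejected because the superlevel set is then the whole
    field, not a tumor.
    """
    if spec.psf_fwhm_mm > 0 or spec.noise_sd > 0:
        raise OutOfRangeError("analytic MTV is defined for the ideal field only")
    if t <= spec.background_suv:
        raise OutOfRangeError("threshold at or below background selects the whole field")
    if t > spec.s_peak:
        return 0.0
    if spec.profile == "uniform":
        return _sphere_ml(spec.radius_mm)
    if spec.profile == "linear_decay":
        r_t = spec.radius_mm * (1.0 - t / spec.s_peak)
        return _sphere_ml(r_t)
    # necrotic_core: whole sphere once the core clears t, else the shell
    if t <= (spec.core_suv or 0.0):
        return _sphere_ml(spec.radius_mm)
    return _sphere_ml(spec.radius_mm) - _sphere_ml(spec.core_radius_mm)


def analytic_hi(
    spec: PhantomSpec, thresholds: list[float], kind: str = "absolute_suv"
) -> float:
    """Closed-form heterogeneity index on a threshold ladder.

    Same abscissa convention as the measured indices: absolute SUV for fixed
    thresholds, percentage points of the peak for fractional ones.
    """
    if kind == "absolute_suv":
        xs = [float(t) for t in thresholds]
        ys = [analytic_mtv(spec, t) for t in thresholds]
    elif kind == "fraction_of_max":
        xs = [100.0 * f for f in thresholds]
        ys = [analytic_mtv(spec, f * spec.s_peak) for f in thresholds]
    else:
        raise ValueError(f"unknown threshold kind {kind!r}")
    hi, _ = heterogeneity_index(xs, ys)
    return hi
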