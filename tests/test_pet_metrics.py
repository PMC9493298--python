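"""Unit and property tests for the SUV metric computations."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pet_hetero.errors import (
    DegenerateRegressionError,
    EmptyVoiError,
    InvalidBoxError,
)
from pet_hetero.pet_metrics import (
    BoundingBox,
    SuvVolume,
    ThresholdSpec,
    Voi,
    compute_all_parameters,
    cv,
    heterogeneity_index,
    mtv,
    mtv_threshold_curve,
    segment_fixed,
    segment_fraction,
    suv_stats,
    tlg,
)
from pet_hetero.phantom import analytic_mtv

from conftest import LINEAR_DECAY_SPEC, UNIFORM_SPEC

SPHERE_20MM_ML = (4.0 / 3.0) * math.pi * 2.0**3  # 33.510 mL


class TestSegmentation:
    def test_uniform_sphere_volume_matches_analytic(self, uniform_volume):
        voi = segment_fixed(uniform_volume, BoundingBox.whole(uniform_volume), 2.5)
        vol_ml = mtv(voi, uniform_volume.spacing)
        assert vol_ml == pytest.approx(SPHERE_20MM_ML, rel=0.02)

    def test_threshold_above_suvmax_raises(self, uniform_volume):
        with pytest.raises(EmptyVoiError):
            segment_fixed(uniform_volume, BoundingBox.whole(uniform_volume), 12.0)

    def test_box_restricts_to_enclosed_sphere(self):
        # two disjoint uptake spheres; the box encloses only the first
        values = np.full((40, 20, 20), 0.5)
        xx, yy, zz = np.ogrid[:40, :20, :20]
        first = (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 36
        second = (xx - 30) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 36
        values[first] = 8.0
        values[second] = 9.0
        volume = SuvVolume(values, (1.0, 1.0, 1.0))
        box = BoundingBox((0, 0, 0), (20, 20, 20))
        voi = segment_fixed(volume, box, 2.5)
        assert voi.mask[first].all()
        assert not voi.mask[second].any()

    def test_connectivity_drops_disconnected_component(self):
        # both spheres inside the box, but only the one holding the maximum
        # survives the connected-component step
        values = np.full((40, 20, 20), 0.5)
        xx, yy, zz = np.ogrid[:40, :20, :20]
        first = (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 36
        second = (xx - 30) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 36
        values[first] = 8.0
        values[second] = 9.0
        volume = SuvVolume(values, (1.0, 1.0, 1.0))
        voi = segment_fixed(volume, BoundingBox.whole(volume), 2.5)
        assert not voi.mask[first].any()
        assert voi.mask[second].all()

    def test_box_exceeding_extent_raises(self, uniform_volume):
        with pytest.raises(InvalidBoxError):
            segment_fixed(
                uniform_volume, BoundingBox((0, 0, 0), (1000, 10, 10)), 2.5
            )

    def test_fraction_resolves_to_absolute(self, uniform_volume):
        box = BoundingBox.whole(uniform_volume)
        frac = segment_fraction(uniform_volume, box, 0.4)
        fixed = segment_fixed(uniform_volume, box, 4.0)
        assert frac.threshold_used.value == pytest.approx(4.0)
        assert np.array_equal(frac.mask, fixed.mask)

    def test_uniform_tumor_fraction_invariant(self, uniform_volume):
        box = BoundingBox.whole(uniform_volume)
        v03 = segment_fraction(uniform_volume, box, 0.3)
        v07 = segment_fraction(uniform_volume, box, 0.7)
        assert v03.n_voxels == v07.n_voxels

    def test_linear_decay_half_max_volume(self, linear_decay_volume):
        # SUV(r) = 10(1 - r/20): half-max isocontour sits at r = 10 mm
        voi = segment_fraction(
            linear_decay_volume, BoundingBox.whole(linear_decay_volume), 0.5
        )
        expected = (4.0 / 3.0) * math.pi * 1.0**3
        assert mtv(voi, linear_decay_volume.spacing) == pytest.approx(expected, rel=0.02)


class TestSuvStatsAndScalars:
    def test_uniform_voi_stats(self, uniform_volume):
        voi = segment_fixed(uniform_volume, BoundingBox.whole(uniform_volume), 2.5)
        stats = suv_stats(uniform_volume, voi)
        assert stats.suv_max == 10.0
        assert stats.suv_mean == 10.0
        assert stats.suv_sd == 0.0

    def test_two_voxel_hand_stats(self, tiny_volume):
        voi = segment_fixed(tiny_volume, BoundingBox.whole(tiny_volume), 2.5)
        stats = suv_stats(tiny_volume, voi)
        assert stats.n_voxels == 2
        assert stats.suv_mean == pytest.approx(5.0)
        assert stats.suv_sd == pytest.approx(math.sqrt(2.0))
        assert cv(tiny_volume, voi) == pytest.approx(math.sqrt(2.0) / 5.0)

    def test_mtv_arithmetic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        voi = Voi(mask=mask, threshold_used=ThresholdSpec("absolute_suv", 2.5))
        assert mtv(voi, (2.0, 2.0, 2.0)) == pytest.approx(8.0)
        empty = Voi(mask=np.zeros((2, 2, 2), dtype=bool),
                    threshold_used=ThresholdSpec("absolute_suv", 2.5))
        assert mtv(empty, (1.0, 1.0, 1.0)) == 0.0

    def test_tlg_product(self):
        assert tlg(10.0, 5.0) == pytest.approx(50.0)
        assert tlg(0.0, 7.3) == 0.0

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.0])
    def test_cv_scale_invariant_on_fixed_voi(self, tiny_volume, k):
        voi = segment_fixed(tiny_volume, BoundingBox.whole(tiny_volume), 2.5)
        scaled = SuvVolume(tiny_volume.values * k, tiny_volume.spacing)
        assert cv(scaled, voi) == pytest.approx(cv(tiny_volume, voi))


class TestHeterogeneityIndex:
    def test_hand_ols_on_analytic_mtvs(self):
        hi, fit = heterogeneity_index(
            (2.5, 3.0, 3.5), (14.137, 11.494, 9.203)
        )
        assert hi == pytest.approx(4.934, abs=1e-3)
        assert fit.slope == pytest.approx(-hi)

    def test_flat_curve_gives_exact_zero(self):
        hi, _ = heterogeneity_index((2.5, 3.0, 3.5), (5.0, 5.0, 5.0))
        assert hi == 0.0

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(42)
        x = np.array([2.5, 3.0, 3.5, 4.0])
        y = rng.uniform(1.0, 30.0, size=4)
        hi, _ = heterogeneity_index(x, y)
        slope_ref = np.polyfit(x, y, 1)[0]
        assert -hi == pytest.approx(slope_ref, abs=1e-9)

    def test_degenerate_abscissa_raises(self):
        with pytest.raises(DegenerateRegressionError):
            heterogeneity_index((3.0, 3.0), (1.0, 2.0))

    @given(
        y1=st.floats(0.1, 100), y2=st.floats(0.1, 100),
        x1=st.floats(1, 5), dx=st.floats(0.5, 5),
    )
    @settings(max_examples=50, derandomize=True)
    def test_two_point_slope_identity(self, y1, y2, x1, dx):
        hi, _ = heterogeneity_index((x1, x1 + dx), (y1, y2))
        assert hi == pytest.approx((y1 - y2) / dx, rel=1e-9, abs=1e-9)

    def test_curve_matches_analytic_radii(self, linear_decay_volume):
        xs, ys = mtv_threshold_curve(
            linear_decay_volume,
            BoundingBox.whole(linear_decay_volume),
            [ThresholdSpec("absolute_suv", t) for t in (2.5, 3.0, 3.5)],
        )
        expected = [analytic_mtv(LINEAR_DECAY_SPEC, t) for t in (2.5, 3.0, 3.5)]
        assert xs == (2.5, 3.0, 3.5)
        for got, want in zip(ys, expected):
            assert got == pytest.approx(want, rel=0.02)

    def test_curve_non_increasing(self, linear_decay_volume):
        _, ys = mtv_threshold_curve(
            linear_decay_volume,
            BoundingBox.whole(linear_decay_volume),
            [ThresholdSpec("fraction_of_max", f) for f in (0.3, 0.4, 0.5, 0.6, 0.7)],
        )
        assert all(a >= b for a, b in zip(ys, ys[1:]))


class TestComputeAllParameters:
    def test_uniform_is_zero_heterogeneity_fixed_point(self, uniform_volume):
        p = compute_all_parameters(uniform_volume, BoundingBox.whole(uniform_volume))
        assert p.cv_2_5 == 0.0
        assert p.cv_40 == 0.0
        assert p.hi_1 == 0.0
        assert p.hi_2 == 0.0
        assert p.mtv_2_5 == p.mtv_40

    def test_tlg_identity(self, linear_decay_volume):
        p = compute_all_parameters(
            linear_decay_volume, BoundingBox.whole(linear_decay_volume)
        )
        voi25 = segment_fixed(
            linear_decay_volume, BoundingBox.whole(linear_decay_volume), 2.5
        )
        mean25 = suv_stats(linear_decay_volume, voi25).suv_mean
        assert p.tlg_2_5 == pytest.approx(p.mtv_2_5 * mean25, rel=1e-9)

    def test_low_uptake_tumor_reports_missing_hi1(self, caplog):
        values = np.full((12, 12, 12), 0.2)
        values[4:8, 4:8, 4:8] = 3.0  # SUVmax below the 3.5 ladder top
        volume = SuvVolume(values, (2.0, 2.0, 2.0))
        with caplog.at_level(logging.WARNING, logger="pet_hetero.pet_metrics"):
            p = compute_all_parameters(volume, BoundingBox.whole(volume))
        assert math.isnan(p.hi_1)
        assert not math.isnan(p.mtv_2_5)
        assert any("MISSING_PARAMETER" in r.message for r in caplog.records)

    def test_scale_equivariance_of_the_three_families(self, linear_decay_volume):
        """cv_40 and hi_2 use relative thresholds and are scale-invariant;
        cv_2_5 and hi_1 use absolute thresholds and are not."""
        k = 1.6
        box = BoundingBox.whole(linear_decay_volume)
        base = compute_all_parameters(linear_decay_volume, box)
        scaled_vol = SuvVolume(
            linear_decay_volume.values * k, linear_decay_volume.spacing
        )
        scaled = compute_all_parameters(scaled_vol, box)
        assert scaled.cv_40 == pytest.approx(base.cv_40, rel=1e-9)
        assert scaled.hi_2 == pytest.approx(base.hi_2, rel=1e-9)
        # absolute 2.5 threshold now cuts at a different isocontour
        assert scaled.cv_2_5 != pytest.approx(base.cv_2_5, rel=1e-3)
        assert scaled.hi_1 != pytest.approx(base.hi_1, rel=1e-3)


@given(t1=st.floats(1.0, 5.0), dt=st.floats(0.1, 4.0))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_mtv_monotone_in_threshold_property(t1, dt):
    """Superlevel sets are nested, so MTV never grows with the threshold."""
    rng = np.random.default_rng(7)
    values = rng.uniform(0.0, 10.0, size=(12, 12, 12))
    values[6, 6, 6] = 10.0  # ensure both thresholds are reachable
    volume = SuvVolume(values, (1.0, 1.0, 1.0))
    box = BoundingBox.whole(volume)
    lo = segment_fixed(volume, box, t1)
    hi = segment_fixed(volume, box, t1 + dt)
    assert mtv(lo, volume.spacing) >= mtv(hi, volume.spacing)
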