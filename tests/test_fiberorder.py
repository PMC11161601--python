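"""Nematic order parameter and structure-tensor orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mechanoquant as mq
from mechanoquant.fiberorder import (
    OrientationField,
    bessel_ratio,
    field_order_parameter,
    invert_order_parameter,
    order_parameter,
    order_tensor,
)
from mechanoquant.synthgen import wrap_axial_deg

angle_lists = st.lists(
    st.floats(min_value=-90.0, max_value=89.999), min_size=1, max_size=60
)


def make_grating(theta_deg, shape=(200, 200), freq=0.1):
    """Stripes along the axis theta (math convention, y up)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    x, y = xx, -yy
    th = np.radians(theta_deg)
    return np.cos(2 * np.pi * freq * (-x * np.sin(th) + y * np.cos(th))) + 1.0


class TestOrderParameter:
    def test_uniform_angles_give_zero(self):
        angles = np.arange(180) - 90.0
        assert order_parameter(angles).S <= 1e-12

    def test_identical_angles_give_one(self):
        res = order_parameter([37.0] * 100)
        assert res.S == 1.0
        assert res.lambda1 == 1.0 and res.lambda2 == -1.0

    def test_two_angle_case_matches_hand_computation(self):
        # <cos2θ> = (1+0)/2, <sin2θ> = (0+1)/2 for θ ∈ {0°, 45°}
        res = order_parameter([0.0, 45.0])
        assert res.mean_cos2 == pytest.approx(0.5, abs=1e-15)
        assert res.mean_sin2 == pytest.approx(0.5, abs=1e-15)
        assert res.S == pytest.approx(np.sqrt(0.5), abs=1e-15)

    def test_empty_and_nan_rejected(self):
        with pytest.raises(ValueError):
            order_parameter([])
        with pytest.raises(ValueError):
            order_parameter([1.0, np.nan])

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            order_parameter([0.0, 10.0], weights=[0.0, 0.0])
        with pytest.raises(ValueError):
            order_parameter([0.0, 10.0], weights=[1.0, -1.0])

    @settings(deadline=None, derandomize=True)
    @given(angle_lists, st.floats(min_value=-360, max_value=360))
    def test_rotation_invariance(self, angles, c):
        a = np.asarray(angles)
        s0 = order_parameter(a).S
        s1 = order_parameter(wrap_axial_deg(a + c)).S
        assert s1 == pytest.approx(s0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(angle_lists)
    def test_axial_periodicity_and_range(self, angles):
        a = np.asarray(angles)
        s0 = order_parameter(a).S
        s180 = order_parameter(a + 180.0).S
        assert s180 == pytest.approx(s0, abs=1e-12)
        assert 0.0 <= s0 <= 1.0 + 1e-12

    def test_eigenvalues_of_order_tensor_reproduce_s(self):
        # oracle: numerical diagonalization of the 2x2 tensor
        rng = np.random.default_rng(0)
        for _ in range(1000):
            angles = rng.uniform(-90, 90, size=rng.integers(2, 40))
            res = order_parameter(angles)
            eig = np.linalg.eigvalsh(order_tensor(angles))
            assert np.max(eig) == pytest.approx(res.S, abs=1e-10)
            assert np.min(eig) == pytest.approx(-res.S, abs=1e-10)

    def test_weighted_average_matches_manual(self):
        angles = [0.0, 90.0]
        res = order_parameter(angles, weights=[3.0, 1.0])
        # <cos2θ> = (3*1 + 1*(-1))/4 = 0.5
        assert res.S == pytest.approx(0.5, abs=1e-15)


class TestStructureTensor:
    @pytest.mark.parametrize("theta", [30.0, -60.0, 0.0, 85.0])
    def test_grating_orientation_recovered(self, theta):
        field = mq.structure_tensor_orientation(make_grating(theta))
        # interior pixels only (border effects)
        inner = np.zeros_like(field.valid)
        inner[20:-20, 20:-20] = True
        vals = field.theta_deg[field.valid & inner]
        # axial median via order-tensor mean axis
        mean_axis = order_parameter(vals).mean_axis_deg
        delta = abs(wrap_axial_deg(mean_axis - theta))
        assert delta <= 1.0

    def test_constant_image_all_invalid(self):
        field = mq.structure_tensor_orientation(np.full((64, 64), 7.0))
        assert not field.valid.any()
        assert field.coherency.max() == 0.0

    def test_rotating_grating_by_90_shifts_theta(self):
        f0 = mq.structure_tensor_orientation(make_grating(20.0))
        f90 = mq.structure_tensor_orientation(make_grating(110.0))  # wraps to -70
        inner = np.zeros_like(f0.valid)
        inner[20:-20, 20:-20] = True
        m0 = order_parameter(f0.theta_deg[f0.valid & inner]).mean_axis_deg
        m90 = order_parameter(f90.theta_deg[f90.valid & inner]).mean_axis_deg
        assert abs(wrap_axial_deg(m90 - m0 - 90.0)) <= 1.0

    def test_coherency_in_unit_interval(self):
        rng = np.random.default_rng(1)
        field = mq.structure_tensor_orientation(rng.uniform(0, 1, (80, 80)))
        assert field.coherency.min() >= 0.0
        assert field.coherency.max() <= 1.0


class TestRimROIs:
    def test_circular_boundary_normals_are_radial(self, disk_organoid):
        org = disk_organoid((500, 500), (249.5, 249.5), 80, pixel_size_um=0.5)
        rois = mq.extract_rim_rois(org, spacing_um=15.0)
        assert len(rois) >= 8
        for roi in rois:
            rad = np.array(roi.anchor) - np.array([249.5, 249.5])
            rad = rad / np.hypot(*rad)
            assert float(np.dot(rad, roi.normal)) >= 0.99

    def test_roi_footprint_units(self):
        roi = mq.RimROI(anchor=(0, 0), normal=(0, 1.0))
        px = 0.5
        assert roi.width_um / px == 60.0
        assert roi.length_um / px == 100.0

    def test_straight_edge_normal(self):
        from skimage import measure

        mask = np.zeros((200, 200), bool)
        mask[:, :100] = True
        contour = measure.find_contours(mask.astype(float), 0.5)[0]
        org = mq.OrganoidMask(
            mask=mask, contour=contour, centroid=(99.5, 49.5),
            equivalent_radius_um=50.0, pixel_size_um=1.0,
        )
        rois = [
            r for r in mq.extract_rim_rois(org, spacing_um=40.0)
            if 30 < r.anchor[0] < 170 and abs(r.anchor[1] - 99.5) < 2
        ]
        assert rois, "no ROIs anchored on the straight edge"
        for roi in rois:
            ang = np.degrees(np.arctan2(roi.normal[0], roi.normal[1]))
            assert abs(ang) <= 2.0  # edge normal is +col

    def test_short_contour_yields_single_roi(self, disk_organoid):
        org = disk_organoid((64, 64), (31.5, 31.5), 10)
        rois = mq.extract_rim_rois(org, spacing_um=1000.0)
        assert len(rois) == 1


class TestRimOrderProfile:
    def test_uniform_iid_field_gives_low_s(self, disk_organoid):
        # per-pixel independent uniform axial angles: S ~ 1/sqrt(n)
        rng = np.random.default_rng(0)
        shape = (500, 500)
        field = OrientationField(
            theta_deg=rng.uniform(-90, 90, shape),
            coherency=np.ones(shape),
            valid=np.ones(shape, bool),
            pixel_size_um=0.5,
        )
        org = disk_organoid(shape, (249.5, 249.5), 80, pixel_size_um=0.5)
        prof = mq.rim_order_profile(field, mq.extract_rim_rois(org, 30.0), 0.5)
        for res in prof.per_roi:
            assert res is not None
            assert res.n_angles >= 2000
            assert res.S <= 0.1

    def test_radial_fibers_give_high_s_per_roi(self, disk_organoid):
        # organoid large relative to the ROI width, so the radial directions
        # inside one 30 µm ROI are nearly parallel
        px = 0.5
        org = disk_organoid((700, 700), (349.5, 349.5), 160, pixel_size_um=px)
        spec = mq.SyntheticFiberSpec(
            n_fibers=6000, orientation_mode="radial", pixel_size_um=px,
            image_shape_px=(700, 700), organoid_center_px=(349.5, 349.5),
            organoid_radius_um=80.0, seed=2, fiber_length_um=10.0,
        )
        img, _ = mq.gen_fiber_field(spec)
        field = mq.structure_tensor_orientation(img["collagen"])
        prof = mq.rim_order_profile(field, mq.extract_rim_rois(org, 30.0), px)
        for res in prof.per_roi:
            assert res is not None and res.S >= 0.95

    def test_empty_roi_reported_missing_not_zero(self):
        shape = (100, 100)
        field = OrientationField(
            theta_deg=np.full(shape, np.nan),
            coherency=np.zeros(shape),
            valid=np.zeros(shape, bool),
            pixel_size_um=1.0,
        )
        roi = mq.RimROI(anchor=(50.0, 50.0), normal=(0.0, 1.0))
        prof = mq.rim_order_profile(field, [roi], 1.0)
        assert prof.per_roi == [None]
        assert prof.pooled is None

    def test_von_mises_field_pooled_s_matches_bessel_ratio(self):
        px = 0.5
        spec = mq.SyntheticFiberSpec(
            kappa=2.0, n_fibers=5000, seed=3, image_shape_px=(2048, 2048), pixel_size_um=px
        )
        img, _ = mq.gen_fiber_field(spec)
        field = mq.structure_tensor_orientation(img["collagen"])
        pooled = field_order_parameter(field)
        assert pooled.S == pytest.approx(bessel_ratio(2.0), abs=0.05)


class TestKappaInversion:
    def test_round_trip_identity(self):
        for kappa in (0.3, 1.0, 4.0, 12.0):
            assert invert_order_parameter(bessel_ratio(kappa)) == pytest.approx(
                kappa, rel=1e-6
            )

    def test_sample_inversion_recovers_generator_kappa(self):
        for kappa in (0.5, 2.0, 8.0):
            spec = mq.SyntheticFiberSpec(kappa=kappa, n_fibers=5000, seed=3)
            _, gt = mq.gen_fiber_field(spec)
            khat = invert_order_parameter(order_parameter(gt.fiber_angles_deg).S)
            assert khat == pytest.approx(kappa, rel=0.15)

    def test_image_route_inversion_at_moderate_kappa(self):
        # measured-field inversion; high kappa is deflated by fiber tips and
        # is covered by the sample route (see docs)
        for kappa in (0.5, 2.0):
            spec = mq.SyntheticFiberSpec(
                kappa=kappa, n_fibers=5000, seed=3, image_shape_px=(2048, 2048)
            )
            img, _ = mq.gen_fiber_field(spec)
            field = mq.structure_tensor_orientation(img["collagen"])
            khat = invert_order_parameter(field_order_parameter(field).S)
            assert khat == pytest.approx(kappa, rel=0.15)
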