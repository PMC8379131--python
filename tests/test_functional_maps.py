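import dataclasses

import numpy as np
import pytest

from vplct.core_io import ScalarVolume, Unit, VesselROI
from vplct.decomposition import DecompositionBasis, decompose
from vplct.errors import NormalizationError, RoiError
from vplct.functional_maps import (
    air_content,
    build_functional_maps,
    normalize_to_vascular,
    regional_ventilation,
)
from vplct.phantom import generate_default_spec, generate_phantom
from vplct.registration import JacobianMap


def _vol(data, unit=Unit.HU, spacing=(1, 1, 1)):
    return ScalarVolume(np.asarray(data, dtype=float), spacing, unit=unit)


def _jac(data):
    return JacobianMap(_vol(data, Unit.DIMENSIONLESS))


class TestAirContent:
    @pytest.mark.parametrize(
        "hu,alpha",
        [(-1000.0, 1.0), (0.0, 0.0), (-742.23, 0.74223), (-500.0, 0.5)],
    )
    def test_linear_map(self, hu, alpha):
        out = air_content(_vol(np.full((4, 4, 4), hu)))
        np.testing.assert_allclose(out.data, alpha, atol=1e-9)
        assert out.unit == Unit.FRACTION

    def test_clamped(self):
        assert air_content(_vol(np.full((4, 4, 4), 500.0))).data.max() == 0.0
        # HU below -1000 cannot exceed air fraction 1
        assert air_content(_vol(np.full((4, 4, 4), -1024.0))).data.max() == 1.0


class TestRegionalVentilation:
    def test_no_volume_change_zero(self):
        s = _jac(np.ones((4, 4, 4)))
        a = _vol(np.full((4, 4, 4), 0.8), Unit.FRACTION)
        rv = regional_ventilation(s, a, a)
        np.testing.assert_allclose(rv.data, 0.0, atol=1e-12)

    def test_total_collapse_one(self):
        s = _jac(np.full((4, 4, 4), 0.7))
        zero = _vol(np.zeros((4, 4, 4)), Unit.FRACTION)
        a = _vol(np.full((4, 4, 4), 0.8), Unit.FRACTION)
        rv = regional_ventilation(s, zero, a)
        np.testing.assert_allclose(rv.data, 1.0, atol=1e-12)

    def test_direct_arithmetic(self):
        s = _jac(np.full((4, 4, 4), 0.6))
        a_exp = _vol(np.full((4, 4, 4), 0.5), Unit.FRACTION)
        a_insp = _vol(np.full((4, 4, 4), 0.75), Unit.FRACTION)
        rv = regional_ventilation(s, a_exp, a_insp)
        np.testing.assert_allclose(rv.data, 0.6, atol=1e-12)

    def test_epsilon_masking(self):
        s = _jac(np.ones((4, 4, 4)))
        a_exp = _vol(np.full((4, 4, 4), 0.5), Unit.FRACTION)
        a_insp = _vol(np.full((4, 4, 4), 0.005), Unit.FRACTION)
        rv = regional_ventilation(s, a_exp, a_insp, epsilon=0.01)
        assert np.isnan(rv.data).all()

    def test_invalid_jacobian_masked(self):
        s_data = np.ones((4, 4, 4))
        s_data[0, 0, 0] = np.nan
        a = _vol(np.full((4, 4, 4), 0.8), Unit.FRACTION)
        rv = regional_ventilation(_jac(s_data), a, a)
        assert np.isnan(rv.data[0, 0, 0])
        assert np.isfinite(rv.data[1:, :, :]).all()

    def test_no_clamping_above_one(self):
        s = _jac(np.full((4, 4, 4), 2.0))  # expansion in expiration
        a = _vol(np.full((4, 4, 4), 0.8), Unit.FRACTION)
        rv = regional_ventilation(s, a, a)
        np.testing.assert_allclose(rv.data, -1.0, atol=1e-12)  # preserved, unclipped


class TestVascularNormalization:
    def _roi(self, shape=(6, 6, 6)):
        labels = np.zeros(shape, dtype=np.int16)
        labels[0, 0, :2] = VesselROI.LABEL_PA_TRUNK
        labels[0, 1, :2] = VesselROI.LABEL_AORTA
        return VesselROI(labels, (1, 1, 1))

    def test_reference_maps_to_100(self):
        pbv = _vol(np.full((6, 6, 6), 250.0), Unit.IODINE_HU)
        out = normalize_to_vascular(pbv, self._roi())
        np.testing.assert_allclose(out.data, 100.0, atol=1e-12)

    def test_half_reference_is_50(self):
        data = np.full((6, 6, 6), 125.0)
        data[self._roi().label_map > 0] = 250.0
        out = normalize_to_vascular(_vol(data, Unit.IODINE_HU), self._roi())
        assert out.data[3, 3, 3] == pytest.approx(50.0)

    def test_mean_of_means(self):
        # PA mean 300, aorta mean 100 -> ref 200 regardless of ROI sizes
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[0, 0, :4] = VesselROI.LABEL_PA_TRUNK
        labels[0, 1, :1] = VesselROI.LABEL_AORTA
        roi = VesselROI(labels, (1, 1, 1))
        data = np.zeros((6, 6, 6))
        data[labels == 1] = 300.0
        data[labels == 2] = 100.0
        data[3, 3, 3] = 200.0
        out = normalize_to_vascular(_vol(data, Unit.IODINE_HU), roi)
        assert out.data[3, 3, 3] == pytest.approx(100.0)

    def test_above_100_unclipped(self):
        data = np.full((6, 6, 6), 300.0)
        data[self._roi().label_map > 0] = 250.0
        out = normalize_to_vascular(_vol(data, Unit.IODINE_HU), self._roi())
        assert out.data[3, 3, 3] == pytest.approx(120.0)

    def test_empty_roi_label(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[0, 0, 0] = VesselROI.LABEL_PA_TRUNK  # aorta missing
        with pytest.raises(RoiError):
            normalize_to_vascular(
                _vol(np.ones((6, 6, 6)), Unit.IODINE_HU), VesselROI(labels, (1, 1, 1))
            )

    def test_nonpositive_reference(self):
        pbv = _vol(np.zeros((6, 6, 6)), Unit.IODINE_HU)
        with pytest.raises(NormalizationError):
            normalize_to_vascular(pbv, self._roi())

    def test_scale_invariance(self, rng):
        data = rng.uniform(10, 400, (6, 6, 6))
        roi = self._roi()
        base = normalize_to_vascular(_vol(data, Unit.IODINE_HU), roi)
        scaled = normalize_to_vascular(_vol(data * 7.3, Unit.IODINE_HU), roi)
        np.testing.assert_allclose(base.data, scaled.data, atol=1e-9)


class TestBuildFunctionalMaps:
    def test_truth_field_ventilation_mae(self, phantom96, decomposed96):
        truth = phantom96["truth"]
        maps = build_functional_maps(
            decomposed96["vnc_insp"], decomposed96["vnc_exp"],
            decomposed96["pbv_insp"], decomposed96["pbv_delayed"],
            truth.displacement_true, truth.vessel_roi_insp, truth.vessel_roi_exp,
        )
        func = np.isin(truth.band_map_exp, [2, 3])
        rv, vt = maps.ventilation.data, truth.ventilation_true.data
        sel = func & np.isfinite(rv) & np.isfinite(vt)
        assert np.abs(rv[sel] - vt[sel]).mean() < 0.02

    def test_registered_field_ventilation_mae(
        self, phantom96, decomposed96, registered_field96
    ):
        truth = phantom96["truth"]
        maps = build_functional_maps(
            decomposed96["vnc_insp"], decomposed96["vnc_exp"],
            decomposed96["pbv_insp"], decomposed96["pbv_delayed"],
            registered_field96, truth.vessel_roi_insp, truth.vessel_roi_exp,
        )
        func = np.isin(truth.band_map_exp, [2, 3])
        rv, vt = maps.ventilation.data, truth.ventilation_true.data
        sel = func & np.isfinite(rv) & np.isfinite(vt)
        assert np.abs(rv[sel] - vt[sel]).mean() < 0.05

    def test_zero_iodine_raises_normalization_error(self):
        spec = generate_default_spec(seed=4, grid_shape=(32, 32, 32))
        spec = dataclasses.replace(
            spec, perfusion_base=0.0, perfusion_blob_boost=0.0,
            vessel_iodine_arterial=0.0, roi_iodine_arterial=(0.0, 0.0),
        )
        il, ih, el, eh, truth = generate_phantom(spec)
        basis = DecompositionBasis(spec.basis)
        vnc_i, pbv_i = decompose(il, ih, basis)
        vnc_e, pbv_d = decompose(el, eh, basis)
        with pytest.raises(NormalizationError):
            build_functional_maps(
                vnc_i, vnc_e, pbv_i, pbv_d, truth.displacement_true,
                truth.vessel_roi_insp, truth.vessel_roi_exp,
            )

    def test_air_volume_bookkeeping(self, phantom96, decomposed96):
        # 1 - RV equals the per-voxel expiration/inspiration air-volume ratio
        truth = phantom96["truth"]
        maps = build_functional_maps(
            decomposed96["vnc_insp"], decomposed96["vnc_exp"],
            decomposed96["pbv_insp"], decomposed96["pbv_delayed"],
            truth.displacement_true, truth.vessel_roi_insp, truth.vessel_roi_exp,
        )
        s = truth.inv_jacobian_true.data
        air_e = -truth.vnc_exp_true.data / 1000.0
        air_i_phi = 1.0 - (1.0 - air_e) * s  # conservation law
        # parenchyma core, eroded so the linear warp stencil never reaches
        # into the interface shells (not part of the bookkeeping contract)
        from scipy import ndimage

        core = ndimage.binary_erosion(
            truth.parenchyma_weight_exp > 0.99, iterations=2
        ) & (air_i_phi > 0.05) & np.isfinite(maps.ventilation.data)
        ratio = s[core] * air_e[core] / air_i_phi[core]
        resid = np.abs((1.0 - maps.ventilation.data[core]) - ratio)
        assert np.percentile(resid, 95) < 1e-3

    def test_basis_invariance_of_ventilation(self, phantom96):
        # RV depends only on the VNC HU and the field, not the basis
        spec = phantom96["spec"]
        truth = phantom96["truth"]
        results = []
        for basis in (
            DecompositionBasis(((1.0, 2.0), (1.0, 1.0))),
            DecompositionBasis(((1.2, 3.1), (0.8, 1.3))),
        ):
            spec2 = dataclasses.replace(spec, basis=tuple(map(tuple, basis.as_array())))
            il, ih, el, eh, tr = generate_phantom(spec2)
            vnc_i, pbv_i = decompose(il, ih, basis)
            vnc_e, pbv_d = decompose(el, eh, basis)
            maps = build_functional_maps(
                vnc_i, vnc_e, pbv_i, pbv_d, tr.displacement_true,
                tr.vessel_roi_insp, tr.vessel_roi_exp,
            )
            results.append(maps.ventilation.data)
        a, b = results
        sel = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(a[sel], b[sel], atol=1e-6)

    def test_late_enhancement_above_100_in_blobs(self, phantom96, decomposed96):
        truth = phantom96["truth"]
        maps = build_functional_maps(
            decomposed96["vnc_insp"], decomposed96["vnc_exp"],
            decomposed96["pbv_insp"], decomposed96["pbv_delayed"],
            truth.displacement_true, truth.vessel_roi_insp, truth.vessel_roi_exp,
        )
        func = np.isin(truth.band_map_exp, [2, 3])
        assert maps.late_enhancement.data[func].max() > 100.0
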