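import numpy as np
import pytest
from scipy import ndimage

from vplct.core_io import DisplacementField, ScalarVolume, Unit
from vplct.errors import DegenerateFieldError, UsageError
from vplct.registration import (
    RegistrationParams,
    inverse_jacobian,
    register,
    registration_qc,
    warp,
)


def _field(vectors, spacing=(1, 1, 1)):
    return DisplacementField(np.asarray(vectors, dtype=float), spacing)


def _affine_field(shape, spacing, grad):
    """u_i = grad[i][j] * x_j on the given grid (mm)."""
    axes = [np.arange(shape[i]) * spacing[i] for i in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    u = np.zeros(shape + (3,))
    for i in range(3):
        for j in range(3):
            u[..., i] += grad[i][j] * g[j]
    return DisplacementField(u, spacing)


class TestInverseJacobian:
    def test_zero_field_identity(self):
        jac = inverse_jacobian(_field(np.zeros((8, 8, 8, 3))))
        np.testing.assert_allclose(jac.data, 1.0, atol=1e-12)
        assert jac.n_folding == 0

    def test_isotropic_expansion_0p512(self):
        grad = [[0.25, 0, 0], [0, 0.25, 0], [0, 0, 0.25]]
        jac = inverse_jacobian(_affine_field((16, 16, 16), (1.0, 1.0, 1.0), grad))
        interior = jac.data[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 1.0 / 1.25**3, rtol=1e-9)
        assert interior[0, 0, 0] == pytest.approx(0.512)

    def test_pure_shear_volume_preserving(self):
        grad = [[0, 0.1, 0], [0, 0, 0], [0, 0, 0]]
        jac = inverse_jacobian(_affine_field((12, 12, 12), (1.0, 1.0, 1.0), grad))
        np.testing.assert_allclose(jac.data, 1.0, atol=1e-9)

    def test_anisotropic_spacing_affine(self, rng):
        # random small affine; oracle = matrix determinant
        a = rng.uniform(-0.1, 0.1, (3, 3))
        spacing = (0.68, 0.68, 1.0)
        jac = inverse_jacobian(_affine_field((14, 14, 14), spacing, a))
        expected = 1.0 / np.linalg.det(np.eye(3) + a)
        interior = jac.data[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, expected, rtol=5e-3)

    def test_folding_masked_not_clamped(self):
        grad = [[-2.0, 0, 0], [0, 0, 0], [0, 0, 0]]  # det = -1 everywhere
        with pytest.raises(DegenerateFieldError):
            inverse_jacobian(_affine_field((8, 8, 8), (1, 1, 1), grad))

    def test_partial_folding_counted(self):
        u = np.zeros((12, 12, 12, 3))
        u[5:7, :, :, 0] = -8.0  # sharp jump folds locally
        jac = inverse_jacobian(_field(u))
        assert jac.n_folding > 0
        assert np.isnan(jac.data[jac.values.data != jac.values.data]).all()


class TestWarp:
    def test_identity_field(self, rng):
        vol = ScalarVolume(rng.normal(size=(8, 8, 8)), (1, 1, 1))
        out = warp(vol, _field(np.zeros((8, 8, 8, 3))))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_pullback_convention(self):
        # step at x >= 5; field u = +1 voxel: output(x) = moving(x+1),
        # so the step appears one voxel earlier in the output frame
        data = np.zeros((10, 6, 6))
        data[5:] = 100.0
        vol = ScalarVolume(data, (1, 1, 1))
        u = np.zeros((10, 6, 6, 3))
        u[..., 0] = 1.0
        out = warp(vol, _field(u))
        assert out.data[4, 3, 3] == pytest.approx(100.0)
        assert out.data[3, 3, 3] == pytest.approx(0.0)

    def test_nearest_for_labels(self, phantom48):
        truth = phantom48["truth"]
        labels = ScalarVolume(
            truth.lung_mask_insp.astype(np.int16), truth.vnc_insp_true.spacing
        )
        out = warp(labels, truth.displacement_true, "nearest")
        assert np.issubdtype(out.data.dtype, np.integer)
        warped = out.data.astype(bool)
        exp = truth.lung_mask_exp
        dice = 2 * (warped & exp).sum() / (warped.sum() + exp.sum())
        assert dice > 0.95

    def test_hu_fill_outside_support(self):
        vol = ScalarVolume(np.zeros((6, 6, 6)), (1, 1, 1), unit=Unit.HU)
        u = np.zeros((6, 6, 6, 3))
        u[..., 0] = 100.0
        out = warp(vol, _field(u))
        np.testing.assert_allclose(out.data, -1024.0)


class TestRegister:
    def test_self_registration_near_zero(self, decomposed96):
        fld = register(decomposed96["vnc_exp"], decomposed96["vnc_exp"])
        assert np.abs(fld.vectors).max() < 0.1

    def test_self_registration_jacobian_near_one(self, decomposed96, phantom96):
        fld = register(decomposed96["vnc_exp"], decomposed96["vnc_exp"])
        s = inverse_jacobian(fld).data
        lung = phantom96["truth"].lung_mask_exp
        frac = ((s[lung] > 0.99) & (s[lung] < 1.01)).mean()
        assert frac >= 0.99

    def test_phantom_field_recovery(self, registered_field96, phantom96):
        truth = phantom96["truth"]
        err = np.linalg.norm(
            registered_field96.vectors - truth.displacement_true.vectors, axis=-1
        )
        assert err[truth.lung_mask_exp].mean() < 1.0

    def test_translation_recovery(self, rng):
        base = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 4) * 2000 - 700
        fixed = ScalarVolume(base, (2, 2, 2), unit=Unit.HU)
        moving = ScalarVolume(np.roll(base, -3, axis=0), (2, 2, 2), unit=Unit.HU)
        fld = register(fixed, moving)
        mean_ux = fld.vectors[10:-10, 10:-10, 10:-10, 0].mean()
        assert abs(mean_ux - (-6.0)) < 0.6  # within 10% of the 3-voxel shift

    def test_mask_volume_ratio_consistency(self, registered_field96, phantom96):
        # voxel-count ratio of lung masks matches the field-integrated ratio
        truth = phantom96["truth"]
        s = inverse_jacobian(registered_field96).data
        lung_e = truth.lung_mask_exp
        vol_ratio_field = np.nanmean(1.0 / s[lung_e])
        vol_ratio_masks = truth.lung_mask_insp.sum() / lung_e.sum()
        assert abs(vol_ratio_field - vol_ratio_masks) / vol_ratio_masks < 0.02


class TestRegistrationQC:
    def test_truth_field_zero_error(self, phantom48):
        truth = phantom48["truth"]
        fld = truth.displacement_true
        # landmarks: fixed points and their true mapped positions
        idx = [(10, 20, 24), (24, 24, 24), (30, 15, 20)]
        rows = []
        for i, j, k in idx:
            x = np.array([i, j, k]) * np.array(fld.spacing)
            rows.append(np.concatenate([x, x + fld.vectors[i, j, k]]))
        report = registration_qc(fld, np.array(rows))
        assert report.max_error_mm < 1e-9
        assert not report.exclude

    def test_exclusion_above_2mm(self):
        fld = _field(np.zeros((8, 8, 8, 3)))
        lm = np.array([[2.0, 2.0, 2.0, 4.5, 2.0, 2.0]])  # 2.5 mm residual
        report = registration_qc(fld, lm)
        assert report.max_error_mm == pytest.approx(2.5)
        assert report.exclude

    def test_exactly_2mm_not_excluded(self):
        fld = _field(np.zeros((8, 8, 8, 3)))
        lm = np.array([[2.0, 2.0, 2.0, 4.0, 2.0, 2.0]])  # exactly 2.0 mm
        report = registration_qc(fld, lm)
        assert report.max_error_mm == pytest.approx(2.0)
        assert not report.exclude

    def test_empty_landmarks_rejected(self):
        fld = _field(np.zeros((8, 8, 8, 3)))
        with pytest.raises(UsageError):
            registration_qc(fld, np.empty((0, 6)))


class TestParams:
    def test_mismatched_levels_rejected(self, decomposed96):
        p = RegistrationParams(shrink_factors=(4, 2), iterations=(10,))
        with pytest.raises(UsageError):
            register(decomposed96["vnc_exp"], decomposed96["vnc_insp"], p)
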