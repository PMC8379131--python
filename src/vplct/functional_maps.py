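"""Voxel-wise functional parameters: ventilation, perfusion, late enhancement.

Regional ventilation combines the inverse-Jacobian shrinkage factor S
with the air-content ratio of the two phases:

    RV = 1 - S * (air_exp / air_insp_warped)

so RV is the fractional air-volume change normalized to inspiration
(0 = no volume change, 1 = total expiratory collapse). The "density" in
the source formulation is read as the air contribution to voxel density
(air content alpha = clamp(-HU/1000, 0, 1)); with mass-conserved tissue
density the expression would be identically zero. RV is deliberately not
clamped: values outside [0, 1] are diagnostic and their fraction is
reported.

Perfusion and late enhancement are iodine maps expressed as a percentage
of the vascular reference, the unweighted mean of the per-ROI means of
the pulmonary-artery trunk and ascending aorta in the same phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import DisplacementField, ScalarVolume, Unit, VesselROI
from .errors import GeometryError, NormalizationError, RoiError
from .registration import JacobianMap, inverse_jacobian, warp

log = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.01


@dataclass
class FunctionalMaps:
    """The per-patient functional volumes plus QC statistics."""

    ventilation: ScalarVolume  # expiration grid, NaN where masked
    perfusion: ScalarVolume  # inspiration grid, percent
    perfusion_warped: ScalarVolume  # expiration grid, percent
    late_enhancement: ScalarVolume  # expiration grid, percent
    vnc_exp: ScalarVolume
    vnc_insp_warped: ScalarVolume
    qc: dict


def air_content(vnc: ScalarVolume) -> ScalarVolume:
    """Air fraction alpha = clamp(-HU/1000, 0, 1)."""
    alpha = np.clip(-np.asarray(vnc.data, dtype=np.float64) / 1000.0, 0.0, 1.0)
    return vnc.with_data(alpha, Unit.FRACTION)


def regional_ventilation(
    inv_jac: JacobianMap,
    air_exp: ScalarVolume,
    air_insp_warped: ScalarVolume,
    epsilon: float = DEFAULT_EPSILON,
) -> ScalarVolume:
    """RV = 1 - S * (air_exp / air_insp_warped), masked where unstable."""
    s = np.asarray(inv_jac.data, dtype=np.float64)
    a_exp = np.asarray(air_exp.data, dtype=np.float64)
    a_insp = np.asarray(air_insp_warped.data, dtype=np.float64)
    if s.shape != a_exp.shape or s.shape != a_insp.shape:
        raise GeometryError("ventilation inputs must share the expiration grid")
    invalid = ~np.isfinite(s) | (a_insp < epsilon)
    safe = np.where(invalid, 1.0, a_insp)
    rv = 1.0 - s * a_exp / safe
    rv = np.where(invalid, np.nan, rv)
    valid = np.isfinite(rv)
    if valid.any():
        outside = float((((rv < 0) | (rv > 1)) & valid).sum() / valid.sum())
        log.info(
            "regional_ventilation: %.4f masked, %.4f outside [0, 1]",
            float(invalid.mean()), outside,
        )
    return ScalarVolume(rv, air_exp.spacing, air_exp.origin, Unit.FRACTION)


def normalize_to_vascular(pbv: ScalarVolume, roi: VesselROI) -> ScalarVolume:
    """Express an iodine map as percent of the vascular reference.

    Reference = (mean over PA-trunk voxels + mean over aorta voxels) / 2,
    taken from the same phase's PBV. Values above 100% are preserved.
    """
    if roi.label_map.shape != pbv.data.shape:
        raise GeometryError("ROI label map not on the PBV grid")
    data = np.asarray(pbv.data, dtype=np.float64)
    means = []
    for label, name in ((roi.LABEL_PA_TRUNK, "PA trunk"), (roi.LABEL_AORTA, "aorta")):
        sel = roi.label_map == label
        if not np.any(sel):
            raise RoiError(f"ROI label {label} ({name}) is empty")
        means.append(float(data[sel].mean()))
    ref = float(np.mean(means))
    if ref <= 0:
        raise NormalizationError(f"vascular reference must be positive, got {ref}")
    return pbv.with_data(100.0 * data / ref, Unit.PERCENT)


def vascular_reference(pbv: ScalarVolume, roi: VesselROI) -> float:
    """The normalization denominator, exposed for QC reporting."""
    data = np.asarray(pbv.data, dtype=np.float64)
    means = []
    for label in (roi.LABEL_PA_TRUNK, roi.LABEL_AORTA):
        sel = roi.label_map == label
        if not np.any(sel):
            raise RoiError(f"ROI label {label} is empty")
        means.append(float(data[sel].mean()))
    return float(np.mean(means))


def build_functional_maps(
    vnc_insp: ScalarVolume,
    vnc_exp: ScalarVolume,
    pbv_insp: ScalarVolume,
    pbv_delayed: ScalarVolume,
    fld: DisplacementField,
    roi_insp: VesselROI,
    roi_delayed: VesselROI | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> FunctionalMaps:
    """Orchestrate the full per-patient map computation.

    Ventilation and late enhancement live on the expiration grid;
    perfusion is computed on the inspiration grid (arterial-phase ROIs)
    and additionally provided warped onto the expiration grid.
    """
    roi_delayed = roi_delayed or roi_insp
    inv_jac = inverse_jacobian(fld)
    vnc_insp_warped = warp(vnc_insp, fld, "linear")
    a_exp = air_content(vnc_exp)
    a_insp_w = air_content(vnc_insp_warped)
    ventilation = regional_ventilation(inv_jac, a_exp, a_insp_w, epsilon)

    perfusion = normalize_to_vascular(pbv_insp, roi_insp)
    perfusion_warped = warp(perfusion, fld, "linear")
    late = normalize_to_vascular(pbv_delayed, roi_delayed)

    rv = ventilation.data
    valid = np.isfinite(rv)
    qc = {
        "masked_fraction": float((~valid).mean()),
        "ventilation_outside_01_fraction": float(
            (((rv < 0) | (rv > 1)) & valid).sum() / max(valid.sum(), 1)
        ),
        "n_folding_voxels": inv_jac.n_folding,
        "vascular_reference_arterial": vascular_reference(pbv_insp, roi_insp),
        "vascular_reference_delayed": vascular_reference(pbv_delayed, roi_delayed),
    }
    return FunctionalMaps(
        ventilation=ventilation,
        perfusion=perfusion,
        perfusion_warped=perfusion_warped,
        late_enhancement=late,
        vnc_exp=vnc_exp,
        vnc_insp_warped=vnc_insp_warped,
        qc=qc,
    )
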