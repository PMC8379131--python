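"""Two-material decomposition of a low/high-kV pair into VNC and iodine.

Per voxel the air-referenced signals solve the linear system

    [low + 1000]   [m00 m01] [tissue]
    [high + 1000] = [m10 m11] [iodine]

and the VNC display value is ``-1000 + m00 * tissue`` (tissue response at
the low-kV reference). Negative iodine solutions are clipped to zero with
the residual reassigned to tissue; the clipped fraction is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ScalarVolume, Unit
from .errors import DataError, GeometryError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecompositionBasis:
    """2x2 material-enhancement matrix.

    Rows: low-kV, high-kV response. Columns: unit tissue, unit iodine
    (HU per unit material). Iodine enhances more at low kV.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 2.0), (1.0, 1.0))

    def __post_init__(self) -> None:
        m = self.as_array()
        if m.shape != (2, 2):
            raise DataError("basis must be 2x2")
        if not np.all(np.isfinite(m)):
            raise DataError("basis contains non-finite entries")
        if abs(np.linalg.det(m)) < 1e-12 or np.linalg.cond(m) >= 1e6:
            raise DataError("basis is singular or ill-conditioned (cond >= 1e6)")
        if not (m[0, 1] > m[1, 1] > 0):
            raise DataError("iodine column must satisfy low-kV > high-kV > 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=np.float64)

    @classmethod
    def from_json_file(cls, path) -> "DecompositionBasis":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(tuple(row) for row in raw["matrix"]))


def decompose(
    low_kv: ScalarVolume,
    high_kv: ScalarVolume,
    basis: DecompositionBasis | None = None,
    clip_negative_iodine: bool = True,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Invert the shared 2x2 forward model into (VNC, iodine) volumes."""
    basis = basis or DecompositionBasis()
    if not low_kv.geometry.matches(high_kv.geometry):
        raise GeometryError("low/high kV volumes are not on the same grid")
    m = basis.as_array()
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    sig_low = np.asarray(low_kv.data, dtype=np.float64) + 1000.0
    sig_high = np.asarray(high_kv.data, dtype=np.float64) + 1000.0
    tissue = (m[1, 1] * sig_low - m[0, 1] * sig_high) / det
    iodine = (m[0, 0] * sig_high - m[1, 0] * sig_low) / det
    if clip_negative_iodine:
        neg = iodine < 0
        frac = float(neg.mean())
        if frac:
            log.info("decompose: clipped negative iodine in %.4f of voxels", frac)
            # residual goes back to tissue, keeping the low-kV signal consistent
            tissue = np.where(neg, sig_low / m[0, 0], tissue)
            iodine = np.where(neg, 0.0, iodine)
    vnc = -1000.0 + m[0, 0] * tissue
    return (
        low_kv.with_data(vnc, Unit.HU),
        low_kv.with_data(iodine, Unit.IODINE_HU),
    )


def pbv_pair(
    insp_pair: tuple[ScalarVolume, ScalarVolume],
    exp_pair: tuple[ScalarVolume, ScalarVolume],
    basis: DecompositionBasis | None = None,
) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume, ScalarVolume]:
    """Decompose both phases: (pbv_insp, pbv_delayed, vnc_insp, vnc_exp).

    The inspiration iodine map is the perfusion surrogate; the delayed
    expiration iodine map carries late enhancement.
    """
    vnc_insp, pbv_insp = decompose(*insp_pair, basis)
    vnc_exp, pbv_delayed = decompose(*exp_pair, basis)
    return pbv_insp, pbv_delayed, vnc_insp, vnc_exp
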