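"""Synthetic digital thorax phantom with fully analytic ground truth.

The phantom defines all anatomy (body ellipsoid, two lung ellipsoids,
fibrotic blobs, vessel cylinders, vascular reference ROIs) as smooth
functions of *inspiration-space* coordinates. The expiration scan is the
pull-back of that anatomy through a closed-form deformation
``phi(x) = c + lam * (x - c) + sinusoid(x)`` whose Jacobian determinant
is available analytically, so every downstream quantity (displacement,
inverse Jacobian, regional ventilation) has an exact oracle.

Air bookkeeping: with per-voxel inspiration air fraction ``a_i`` and
incompressible tissue, mass conservation fixes the expiration air
fraction ``a_e = 1 - (1 - a_i)/S`` where ``S = 1/det(Dphi)`` is the
shrinkage factor, and the regional ventilation truth is
``v = (1 - S) / a_i``. Voxel HU is ``-1000 * air_fraction`` inside the
parenchyma so that the linear air-content mapping is exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import DisplacementField, ScalarVolume, Unit, VesselROI
from .errors import SpecError, UsageError

LABEL_OUTSIDE = 0
LABEL_LAA = 1
LABEL_NAA = 2
LABEL_HAA = 3
LABEL_EXCLUDED = 4

DEFAULT_BASIS = ((1.0, 2.0), (1.0, 1.0))  # rows low/high kV, cols tissue/iodine


@dataclass
class Blob:
    """Gaussian fibrotic lesion: reduces air fraction, boosts iodine."""

    center_mm: tuple[float, float, float]
    sigma_mm: float
    air_drop: float  # peak reduction of inspiration air fraction

    def profile(self, x, y, z) -> np.ndarray:
        r2 = (
            (x - self.center_mm[0]) ** 2
            + (y - self.center_mm[1]) ** 2
            + (z - self.center_mm[2]) ** 2
        )
        return np.exp(-r2 / (2.0 * self.sigma_mm**2))


def _sigmoid(d: np.ndarray, edge_mm: float) -> np.ndarray:
    """Smooth inside-weight from a signed distance (negative = inside)."""
    return 1.0 / (1.0 + np.exp(np.clip(4.0 * d / edge_mm, -60.0, 60.0)))


@dataclass
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def signed_distance(self, x, y, z) -> np.ndarray:
        """Approximate signed distance (mm), negative inside."""
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semiaxes_mm
        r = np.sqrt(
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        )
        return (r - 1.0) * min(ax, ay, az)

    def inside(self, x, y, z) -> np.ndarray:
        return self.signed_distance(x, y, z) <= 0.0


@dataclass
class Cylinder:
    """Axis-aligned (z) vessel cylinder."""

    center_xy_mm: tuple[float, float]
    radius_mm: float
    z_range_mm: tuple[float, float]

    def signed_distance(self, x, y, z) -> np.ndarray:
        dr = (
            np.sqrt(
                (x - self.center_xy_mm[0]) ** 2 + (y - self.center_xy_mm[1]) ** 2
            )
            - self.radius_mm
        )
        dz = np.maximum(self.z_range_mm[0] - z, z - self.z_range_mm[1])
        return np.maximum(dr, dz)

    def inside(self, x, y, z) -> np.ndarray:
        return self.signed_distance(x, y, z) <= 0.0


@dataclass
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def signed_distance(self, x, y, z) -> np.ndarray:
        r = np.sqrt(
            (x - self.center_mm[0]) ** 2
            + (y - self.center_mm[1]) ** 2
            + (z - self.center_mm[2]) ** 2
        )
        return r - self.radius_mm

    def inside(self, x, y, z) -> np.ndarray:
        return self.signed_distance(x, y, z) <= 0.0


@dataclass
class PhantomSpec:
    """Full parametrization of one synthetic two-phase dual-energy dataset."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    body: Ellipsoid | None = None
    lungs: list[Ellipsoid] = field(default_factory=list)

    # inspiration air-fraction model
    air_base: float = 0.85
    air_sin_amp: float = 0.025
    air_sin_freq_mm: tuple[float, float, float] = (0.032, 0.040, 0.026)
    air_grad_per_mm: float = 0.0002  # gravity-like craniocaudal gradient
    fibrosis_blobs: list[Blob] = field(default_factory=list)

    # deformation phi(x) = c + lam*(x-c) + amp*sin(w*(x-c)) (+ shear in x)
    # sinusoid is low-frequency with amp*2*pi*freq << lam - 1 so that the
    # shrinkage S stays below 1 throughout the lung (ventilation >= 0)
    deform_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lam: tuple[float, float, float] = (1.16, 1.16, 1.16)
    sin_amp_mm: tuple[float, float, float] = (0.8, 0.8, 1.0)
    sin_freq_mm: tuple[float, float, float] = (0.008, 0.009, 0.007)
    shear_amp_mm: float = 0.8
    shear_freq_mm: float = 0.008

    # iodine model (iodine-HU units)
    vessels: list[Cylinder] = field(default_factory=list)
    roi_pa: Sphere | None = None
    roi_aorta: Sphere | None = None
    perfusion_base: float = 25.0
    perfusion_blob_boost: float = 12.0
    delayed_base: float = 45.0
    delayed_blob_boost: float = 130.0
    vessel_iodine_arterial: float = 320.0
    vessel_iodine_delayed: float = 150.0
    roi_iodine_arterial: tuple[float, float] = (320.0, 280.0)  # (PA, aorta)
    roi_iodine_delayed: tuple[float, float] = (150.0, 130.0)

    basis: tuple = DEFAULT_BASIS
    noise_hu: float = 0.0
    edge_mm: float = 3.0  # sigmoid width of anatomical interfaces (PSF stand-in)

    def validate(self) -> None:
        if self.body is None or len(self.lungs) != 2:
            raise SpecError("spec needs a body ellipsoid and exactly two lungs")
        if not (0.0 < self.air_base < 1.0):
            raise SpecError("air_base must lie in (0, 1)")
        for i in range(3):
            # diagonal Jacobian entries lam_i + amp_i*w_i*cos(...) must stay > 0
            wiggle = self.sin_amp_mm[i] * 2 * np.pi * self.sin_freq_mm[i]
            if self.lam[i] - wiggle <= 0:
                raise SpecError(
                    f"deformation axis {i} not diffeomorphic: "
                    f"lam={self.lam[i]} wiggle={wiggle:.3f}"
                )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {"__cls__": type(obj).__name__, **dataclasses.asdict(obj)}
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        raw = json.loads(text)
        raw["body"] = Ellipsoid(**_tup(raw["body"])) if raw.get("body") else None
        raw["lungs"] = [Ellipsoid(**_tup(d)) for d in raw.get("lungs", [])]
        raw["fibrosis_blobs"] = [Blob(**_tup(d)) for d in raw.get("fibrosis_blobs", [])]
        raw["vessels"] = [Cylinder(**_tup(d)) for d in raw.get("vessels", [])]
        for key in ("roi_pa", "roi_aorta"):
            raw[key] = Sphere(**_tup(raw[key])) if raw.get(key) else None
        for key in (
            "grid_shape", "spacing", "deform_center_mm", "lam", "sin_amp_mm",
            "sin_freq_mm", "air_sin_freq_mm", "roi_iodine_arterial",
            "roi_iodine_delayed",
        ):
            raw[key] = tuple(raw[key])
        raw["basis"] = tuple(tuple(row) for row in raw["basis"])
        return cls(**raw)


def _tup(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    displacement_true: DisplacementField
    inv_jacobian_true: ScalarVolume
    ventilation_true: ScalarVolume  # NaN outside expiration parenchyma
    vnc_insp_true: ScalarVolume
    vnc_exp_true: ScalarVolume
    iodine_insp_true: ScalarVolume
    iodine_delayed_true: ScalarVolume
    lung_mask_insp: np.ndarray
    lung_mask_exp: np.ndarray
    band_map_insp: np.ndarray
    band_map_exp: np.ndarray
    vessel_roi_insp: VesselROI
    vessel_roi_exp: VesselROI
    mean_ventilation: float
    # smooth parenchyma weights (for O(h^2) integral bookkeeping)
    parenchyma_weight_insp: np.ndarray | None = None
    parenchyma_weight_exp: np.ndarray | None = None


# ---------------------------------------------------------------------------
# spec builders


def _base_geometry(grid_shape, spacing):
    extent = np.array(grid_shape) * np.array(spacing)
    c = extent / 2.0
    body = Ellipsoid(tuple(c), tuple(extent * np.array([0.42, 0.36, 0.44])))
    dx = extent[0] * 0.20
    semi = tuple(extent * np.array([0.15, 0.24, 0.32]))
    lungs = [
        Ellipsoid((c[0] - dx, c[1], c[2]), semi),
        Ellipsoid((c[0] + dx, c[1], c[2]), semi),
    ]
    return c, extent, body, lungs


def _vessels_and_rois(c, extent, lungs):
    vessels = []
    for lung in lungs:
        cx, cy, cz = lung.center_mm
        az = lung.semiaxes_mm[2]
        vessels.append(
            Cylinder((cx, cy), extent[0] * 0.018, (cz - 0.55 * az, cz + 0.55 * az))
        )
    r = extent[0] * 0.045
    roi_pa = Sphere((c[0], c[1] - 1.8 * r, c[2]), r)
    roi_aorta = Sphere((c[0], c[1] + 1.8 * r, c[2]), r)
    return vessels, roi_pa, roi_aorta


def lam_for_mean_ventilation(target: float, air_base: float) -> float:
    """Isotropic expansion factor giving shrinkage S = 1 - target*air_base."""
    s = 1.0 - target * air_base
    if s <= 0:
        raise SpecError(f"target ventilation {target} infeasible for air {air_base}")
    return float(s ** (-1.0 / 3.0))


def generate_default_spec(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    target_mean_ventilation: float = 0.40,
    n_blobs: int = 3,
) -> PhantomSpec:
    """Fibrotic-lung spec: HAA blobs with elevated delayed enhancement."""
    rng = np.random.default_rng(seed)
    spacing = tuple(192.0 / np.array(grid_shape))
    c, extent, body, lungs = _base_geometry(grid_shape, spacing)
    vessels, roi_pa, roi_aorta = _vessels_and_rois(c, extent, lungs)

    blobs = []
    for i in range(n_blobs):
        lung = lungs[i % 2]
        off = rng.uniform(-0.4, 0.4, size=3) * np.array(lung.semiaxes_mm)
        blobs.append(
            Blob(
                tuple(np.array(lung.center_mm) + off),
                sigma_mm=float(rng.uniform(0.09, 0.13) * extent[0]),
                air_drop=float(rng.uniform(0.30, 0.34)),
            )
        )

    lam = lam_for_mean_ventilation(target_mean_ventilation, 0.85)
    spec = PhantomSpec(
        grid_shape=tuple(int(n) for n in grid_shape),
        spacing=spacing,
        seed=int(seed),
        body=body,
        lungs=lungs,
        fibrosis_blobs=blobs,
        deform_center_mm=tuple(c),
        lam=(lam, lam, lam),
        vessels=vessels,
        roi_pa=roi_pa,
        roi_aorta=roi_aorta,
    )
    spec.validate()
    return spec


def generate_healthy_spec(
    seed: int, grid_shape: tuple[int, int, int] = (64, 64, 64)
) -> PhantomSpec:
    """Spec whose prescribed mean ventilation lies in the healthy 0.40-0.50 band."""
    rng = np.random.default_rng(seed)
    # realized mean sits above target (Jensen on 1/air, boundary blends);
    # sample conservatively so all seeds stay inside the 0.40-0.50 band
    target = float(rng.uniform(0.385, 0.42))
    spacing = tuple(192.0 / np.array(grid_shape))
    c, extent, body, lungs = _base_geometry(grid_shape, spacing)
    vessels, roi_pa, roi_aorta = _vessels_and_rois(c, extent, lungs)
    lam = lam_for_mean_ventilation(target, 0.85)
    spec = PhantomSpec(
        grid_shape=tuple(int(n) for n in grid_shape),
        spacing=spacing,
        seed=int(seed),
        body=body,
        lungs=lungs,
        fibrosis_blobs=[],
        air_sin_amp=0.02,
        deform_center_mm=tuple(c),
        lam=(lam, lam, lam),
        sin_amp_mm=(0.6, 0.6, 0.8),
        vessels=vessels,
        roi_pa=roi_pa,
        roi_aorta=roi_aorta,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# analytic fields


def _deformation(spec: PhantomSpec, x, y, z):
    """phi(x) and analytic det(Dphi) on the expiration grid."""
    cx, cy, cz = spec.deform_center_mm
    lam = spec.lam
    amp = spec.sin_amp_mm
    w = tuple(2 * np.pi * f for f in spec.sin_freq_mm)
    dxs, dys, dzs = x - cx, y - cy, z - cz
    phix = cx + lam[0] * dxs + amp[0] * np.sin(w[0] * dxs)
    phiy = cy + lam[1] * dys + amp[1] * np.sin(w[1] * dys)
    phiz = cz + lam[2] * dzs + amp[2] * np.sin(w[2] * dzs)
    # shear: x-displacement driven by y; upper-triangular Jacobian, det unchanged
    ws = 2 * np.pi * spec.shear_freq_mm
    phix = phix + spec.shear_amp_mm * np.sin(ws * dys)
    jx = lam[0] + amp[0] * w[0] * np.cos(w[0] * dxs)
    jy = lam[1] + amp[1] * w[1] * np.cos(w[1] * dys)
    jz = lam[2] + amp[2] * w[2] * np.cos(w[2] * dzs)
    det = jx * jy * jz
    return phix, phiy, phiz, det


def _air_fraction_insp(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Inspiration air fraction of the parenchyma at points (x, y, z)."""
    w = tuple(2 * np.pi * f for f in spec.air_sin_freq_mm)
    cx, cy, cz = spec.deform_center_mm
    a = spec.air_base + spec.air_sin_amp * (
        np.sin(w[0] * (x - cx)) * np.sin(w[1] * (y - cy))
        + 0.5 * np.sin(w[2] * (z - cz) + 1.0)
    )
    a = a + spec.air_grad_per_mm * (z - cz)
    if spec.fibrosis_blobs:
        # overlapping lesions do not stack: deepest drop wins
        drop = np.zeros(np.shape(x))
        for blob in spec.fibrosis_blobs:
            drop = np.maximum(drop, blob.air_drop * blob.profile(x, y, z))
        a = a - drop
    return np.clip(a, 0.15, 0.98)


def _weights(spec: PhantomSpec, x, y, z):
    """Smooth inside-weights of all anatomical structures at points (x,y,z)."""
    e = spec.edge_mm
    w_body = _sigmoid(spec.body.signed_distance(x, y, z), e)
    w_lung = np.zeros(x.shape)
    for ell in spec.lungs:
        w_lung = np.maximum(w_lung, _sigmoid(ell.signed_distance(x, y, z), e))
    w_vessel = np.zeros(x.shape)
    for cyl in spec.vessels:
        w_vessel = np.maximum(w_vessel, _sigmoid(cyl.signed_distance(x, y, z), e))
    w_pa = _sigmoid(spec.roi_pa.signed_distance(x, y, z), e)
    w_ao = _sigmoid(spec.roi_aorta.signed_distance(x, y, z), e)
    return w_body, w_lung, w_vessel, w_pa, w_ao


def _anatomy(spec: PhantomSpec, x, y, z, arterial: bool):
    """Air fraction, iodine field, and crisp masks at insp-space points.

    All non-air material is water-equivalent (0 HU), so voxel HU is
    ``-1000 * air_fraction`` and the linear air-content map is exact.
    """
    w_body, w_lung, w_vessel, w_pa, w_ao = _weights(spec, x, y, z)
    alpha_par = _air_fraction_insp(spec, x, y, z)
    parench = w_body * w_lung * (1.0 - w_vessel)
    air = (1.0 - w_body) + parench * alpha_par

    boost = _blob_boost(spec, x, y, z)
    if arterial:
        lung_iod = spec.perfusion_base + spec.perfusion_blob_boost * boost
        vessel_iod, (pa_iod, ao_iod) = spec.vessel_iodine_arterial, spec.roi_iodine_arterial
    else:
        lung_iod = spec.delayed_base + spec.delayed_blob_boost * boost
        vessel_iod, (pa_iod, ao_iod) = spec.vessel_iodine_delayed, spec.roi_iodine_delayed
    iodine = w_body * (
        w_lung * ((1.0 - w_vessel) * lung_iod + w_vessel * vessel_iod)
        + (1.0 - w_lung) * (w_pa * pa_iod + w_ao * ao_iod)
    )

    lung_mask = (w_body > 0.5) & (w_lung > 0.5) & (w_vessel <= 0.5)
    roi = np.zeros(x.shape, dtype=np.int16)
    roi[(w_pa > 0.5) & (w_lung <= 0.5)] = VesselROI.LABEL_PA_TRUNK
    roi[(w_ao > 0.5) & (w_lung <= 0.5)] = VesselROI.LABEL_AORTA
    return air, iodine, lung_mask, roi, parench


def _blob_boost(spec: PhantomSpec, x, y, z) -> np.ndarray:
    boost = np.zeros(x.shape)
    for blob in spec.fibrosis_blobs:
        boost = np.maximum(boost, blob.profile(x, y, z))
    return boost


def _classify_hu(hu: np.ndarray, lung: np.ndarray) -> np.ndarray:
    labels = np.zeros(hu.shape, dtype=np.int16)
    labels[lung & (hu < -950)] = LABEL_LAA
    labels[lung & (hu >= -950) & (hu < -600)] = LABEL_NAA
    labels[lung & (hu >= -600) & (hu < -250)] = LABEL_HAA
    labels[lung & (hu >= -250)] = LABEL_EXCLUDED
    return labels


# ---------------------------------------------------------------------------
# generator


def generate_phantom(spec: PhantomSpec):
    """Synthesize the four kV volumes plus ground truth.

    Returns ``(insp_low, insp_high, exp_low, exp_high, truth)``. The
    inspiration pair is the arterial phase, the expiration pair the
    5-minute delayed phase; low/high kV are built from the shared
    two-material forward model so decomposition inverts them exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geom_x, geom_y, geom_z = _grid_mm(spec)
    spacing = tuple(float(s) for s in spec.spacing)

    # ---- inspiration (arterial) phase: anatomy sampled at identity -------
    air_i, iod_i, lung_i, roi_map_i, wpar_i = _anatomy(
        spec, geom_x, geom_y, geom_z, arterial=True
    )
    vnc_i = -1000.0 * air_i

    # ---- expiration (delayed) phase: pull-back through phi ---------------
    phix, phiy, phiz, det = _deformation(spec, geom_x, geom_y, geom_z)
    shrink = 1.0 / det  # S = expiration volume / inspiration volume
    air_i_at_phi, iod_e, lung_e, roi_map_e, wpar_e = _anatomy(
        spec, phix, phiy, phiz, arterial=False
    )

    if np.any(det[lung_e] <= 0):
        raise SpecError("deformation folds inside the lung support")
    # mass conservation: (1 - air_e) * S = 1 - air_i  (incompressible tissue);
    # the clamp only engages in interface shells and outside the lung, where
    # tissue does not compress
    air_e = np.clip(1.0 - (1.0 - air_i_at_phi) / shrink, 0.0, 1.0)
    vnc_e = -1000.0 * air_e
    # truth = exactly what an ideal pipeline computes from these images
    vent = 1.0 - shrink * air_e / np.maximum(air_i_at_phi, 1e-9)
    # invariant check on the saturated parenchyma core (edge blends excluded)
    core = wpar_e > 0.99
    if np.any(vent[core] < 0) or np.any(vent[core] >= 1):
        raise SpecError(
            "prescribed ventilation leaves [0, 1); adjust lam/air parameters "
            f"(range {vent[core].min():.3f}..{vent[core].max():.3f})"
        )
    if np.any(air_e[core] <= 0):
        raise SpecError("expiration air fraction non-positive; contraction too strong")

    # ---- shared two-material forward model -------------------------------
    basis = np.asarray(spec.basis, dtype=np.float64)
    insp_low, insp_high = _forward_kv(vnc_i, iod_i, basis)
    exp_low, exp_high = _forward_kv(vnc_e, iod_e, basis)
    if spec.noise_hu > 0:
        for img in (insp_low, insp_high, exp_low, exp_high):
            img += rng.normal(0.0, spec.noise_hu, size=img.shape)

    vent_map = np.where(lung_e, vent, np.nan)
    ux = phix - geom_x
    uy = phiy - geom_y
    uz = phiz - geom_z

    truth = PhantomTruth(
        displacement_true=DisplacementField(np.stack([ux, uy, uz], axis=-1), spacing),
        inv_jacobian_true=ScalarVolume(shrink, spacing, unit=Unit.DIMENSIONLESS),
        ventilation_true=ScalarVolume(vent_map, spacing, unit=Unit.FRACTION),
        vnc_insp_true=ScalarVolume(vnc_i, spacing, unit=Unit.HU),
        vnc_exp_true=ScalarVolume(vnc_e, spacing, unit=Unit.HU),
        iodine_insp_true=ScalarVolume(iod_i, spacing, unit=Unit.IODINE_HU),
        iodine_delayed_true=ScalarVolume(iod_e, spacing, unit=Unit.IODINE_HU),
        lung_mask_insp=lung_i,
        lung_mask_exp=lung_e,
        band_map_insp=_classify_hu(vnc_i, lung_i),
        band_map_exp=_classify_hu(-1000.0 * air_i_at_phi, lung_e),
        vessel_roi_insp=VesselROI(roi_map_i, spacing),
        vessel_roi_exp=VesselROI(roi_map_e, spacing),
        mean_ventilation=float(np.nanmean(vent_map)),
        parenchyma_weight_insp=wpar_i,
        parenchyma_weight_exp=wpar_e,
    )

    def vol(arr):
        return ScalarVolume(arr, spacing, unit=Unit.HU)

    return vol(insp_low), vol(insp_high), vol(exp_low), vol(exp_high), truth


def _grid_mm(spec: PhantomSpec):
    axes = [np.arange(spec.grid_shape[i]) * spec.spacing[i] for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _forward_kv(vnc: np.ndarray, iodine: np.ndarray, basis: np.ndarray):
    """Map (VNC HU, iodine) to the low/high-kV pair via the 2x2 basis."""
    tissue = (vnc + 1000.0) / basis[0, 0]
    low = -1000.0 + basis[0, 0] * tissue + basis[0, 1] * iodine
    high = -1000.0 + basis[1, 0] * tissue + basis[1, 1] * iodine
    return low, high


# ---------------------------------------------------------------------------
# cohort generator

COHORT_COLUMNS = [
    "patient_id", "interval_days",
    "ventilation_b", "perfusion_b", "late_enhancement_b",
    "fvc_pct_b", "fvc_pct_f", "dlco_pct_b", "dlco_pct_f",
    "lung_volume_ml_b", "lung_volume_ml_f",
    "lung_density_hu_b", "lung_density_hu_f",
]


def generate_cohort(
    n_patients: int,
    planted_r: float,
    noise_sd: float,
    seed: int,
    dlco_missing_fraction: float = 6.0 / 32.0,
) -> pd.DataFrame:
    """Cohort table with a planted linear relation between baseline mean
    ventilation and the annualized follow-up/baseline lung-volume ratio.

    ``planted_r`` is the population correlation; ``noise_sd`` scales the
    stochastic part of the annualized ratio (0 makes the ratio column
    degenerate/constant, which downstream statistics must flag).
    """
    if n_patients < 4:
        raise UsageError("cohort needs at least 4 patients")
    if not (-1.0 < planted_r < 1.0):
        raise UsageError("planted_r must lie strictly inside (-1, 1)")
    if noise_sd < 0:
        raise UsageError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    z_vent = rng.standard_normal(n_patients)
    z_noise = rng.standard_normal(n_patients)
    vent = 0.63 + 0.10 * z_vent
    # annualized volume ratio; correlation with vent is planted_r by construction
    ratio_ann = 0.94 + noise_sd * (
        planted_r * z_vent + np.sqrt(1.0 - planted_r**2) * z_noise
    )
    interval_days = np.round(
        np.maximum(rng.normal(456.0, 120.0, n_patients), 190.0), 1
    )
    vol_b = rng.normal(3942.0, 844.0, n_patients).clip(1500.0)
    # invert the 1-year normalization to obtain raw follow-up volumes
    vol_f = vol_b * (1.0 + (ratio_ann - 1.0) * interval_days / 365.25)

    fvc_b = rng.normal(69.8, 17.3, n_patients).clip(20.0)
    fvc_f = fvc_b * rng.normal(0.95, 0.08, n_patients)
    dlco_b = rng.normal(52.6, 14.6, n_patients).clip(15.0)
    dlco_f = dlco_b * rng.normal(0.90, 0.10, n_patients)
    dens_b = rng.normal(-742.0, 51.0, n_patients)
    dens_f = dens_b + rng.normal(14.0, 25.0, n_patients)
    perf = rng.normal(9.02, 2.12, n_patients).clip(2.0)
    late = rng.normal(38.0, 11.6, n_patients).clip(5.0)

    n_missing = int(round(dlco_missing_fraction * n_patients))
    missing = rng.choice(n_patients, size=n_missing, replace=False)
    dlco_b[missing] = np.nan
    dlco_f[missing] = np.nan

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
            "interval_days": interval_days,
            "ventilation_b": vent,
            "perfusion_b": perf,
            "late_enhancement_b": late,
            "fvc_pct_b": fvc_b,
            "fvc_pct_f": fvc_f,
            "dlco_pct_b": dlco_b,
            "dlco_pct_f": dlco_f,
            "lung_volume_ml_b": vol_b,
            "lung_volume_ml_f": vol_f,
            "lung_density_hu_b": dens_b,
            "lung_density_hu_f": dens_f,
        }
    )


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"cohort table missing columns: {missing}")
    return df
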