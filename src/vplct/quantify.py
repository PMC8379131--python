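"""Per-patient scalar summaries: band-wise means, lung volume, histograms."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .core_io import ScalarVolume
from .errors import EmptyRegionError, GeometryError, UsageError
from .masking import LABEL_HAA, LABEL_NAA, BandLabelMap

REGIONS = ("functional", "NAA", "HAA")

DEFAULT_HIST_RANGES = {
    "ventilation": (0.0, 1.2),
    "perfusion": (0.0, 30.0),
    "late_enhancement": (0.0, 130.0),
}
DEFAULT_HIST_BINS = 50


def _region_mask(bands: BandLabelMap, region: str) -> np.ndarray:
    if region == "functional":
        return bands.functional_mask
    if region == "NAA":
        return bands.labels == LABEL_NAA
    if region == "HAA":
        return bands.labels == LABEL_HAA
    raise UsageError(f"unknown region {region!r}")


def region_mean(vol: ScalarVolume, bands: BandLabelMap, region: str) -> float:
    """Mean over valid (finite) voxels of the requested band region."""
    if vol.data.shape != bands.labels.shape:
        raise GeometryError("map and band label grids differ")
    sel = _region_mask(bands, region)
    vals = np.asarray(vol.data, dtype=np.float64)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRegionError(f"region {region!r} has no valid voxels")
    return float(vals.mean())


def lung_volume_and_density(
    vnc_insp: ScalarVolume, lung_mask: np.ndarray
) -> tuple[float, float]:
    """(lung volume in mL, mean lung density in HU) within the mask."""
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != vnc_insp.data.shape:
        raise GeometryError("mask shape does not match the volume")
    n = int(lung_mask.sum())
    if n == 0:
        raise EmptyRegionError("lung mask is empty")
    volume_ml = n * vnc_insp.geometry.voxel_volume_mm3 / 1000.0
    density = float(np.asarray(vnc_insp.data, dtype=np.float64)[lung_mask].mean())
    return float(volume_ml), density


def histogram(
    vol: ScalarVolume, region_mask: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Counts per bin over valid region voxels; ends are open-ended.

    Values below the first / above the last edge are folded into the
    first / last bin, so counts always sum to the valid voxel count.
    """
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise UsageError("edges must be a strictly increasing 1D array (>= 2 values)")
    vals = np.asarray(vol.data, dtype=np.float64)[np.asarray(region_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts


@dataclass
class PatientSummary:
    mean_ventilation: dict[str, float]
    mean_perfusion: dict[str, float]
    mean_late_enhancement: dict[str, float]
    lung_volume_ml: float
    mean_lung_density_hu: float
    functional_fraction: float
    n_masked_voxels: int
    histograms: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_patient(
    ventilation: ScalarVolume,
    perfusion: ScalarVolume,
    late_enhancement: ScalarVolume,
    bands: BandLabelMap,
    vnc_insp: ScalarVolume,
    lung_mask_insp: np.ndarray,
    bands_insp: BandLabelMap | None = None,
    hist_bins: int = DEFAULT_HIST_BINS,
) -> PatientSummary:
    """All PatientSummary scalars from the functional maps.

    ``bands`` must be on the grid of the ventilation/late-enhancement
    maps (expiration). Perfusion lives on the inspiration grid, so pass
    ``bands_insp`` when it differs; otherwise ``bands`` is used.
    """
    from .masking import functional_fraction as _ff

    perf_bands = bands_insp or bands
    means = {}
    for name, vol, bnd in (
        ("ventilation", ventilation, bands),
        ("perfusion", perfusion, perf_bands),
        ("late_enhancement", late_enhancement, bands),
    ):
        means[name] = {r: region_mean(vol, bnd, r) for r in REGIONS}

    volume_ml, density = lung_volume_and_density(vnc_insp, lung_mask_insp)
    hists = {}
    for name, vol, bnd in (
        ("ventilation", ventilation, bands),
        ("perfusion", perfusion, perf_bands),
        ("late_enhancement", late_enhancement, bands),
    ):
        lo, hi = DEFAULT_HIST_RANGES[name]
        edges = np.linspace(lo, hi, hist_bins + 1)
        hists[name] = {
            "edges": edges.tolist(),
            "counts": histogram(vol, bnd.functional_mask, edges).tolist(),
        }
    n_masked = int(
        np.count_nonzero(~np.isfinite(ventilation.data) & bands.functional_mask)
    )
    return PatientSummary(
        mean_ventilation=means["ventilation"],
        mean_perfusion=means["perfusion"],
        mean_late_enhancement=means["late_enhancement"],
        lung_volume_ml=volume_ml,
        mean_lung_density_hu=density,
        functional_fraction=_ff(bands_insp or bands),
        n_masked_voxels=n_masked,
        histograms=hists,
    )
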