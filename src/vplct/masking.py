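"""Lung segmentation and HU-band classification.

Segmentation is a classical threshold + connected-component substitute
for a learned model: candidate voxels below -320 HU, background air
removed as the component touching the volume border, the two largest
remaining components kept, holes filled.

Band labels (half-open intervals, inspiration VNC HU):
    1 LAA       HU < -950
    2 NAA       -950 <= HU < -600
    3 HAA       -600 <= HU < -250
    4 excluded  HU >= -250 (vessels, dense fibrosis)
NAA + HAA form the functional lung tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import ScalarVolume
from .errors import EmptyRegionError, GeometryError, SegmentationError

LUNG_THRESHOLD_HU = -320.0
BAND_EDGES = (-950.0, -600.0, -250.0)

LABEL_OUTSIDE = 0
LABEL_LAA = 1
LABEL_NAA = 2
LABEL_HAA = 3
LABEL_EXCLUDED = 4


@dataclass
class BandLabelMap:
    """Per-voxel band labels on the grid of the source VNC volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    band_edges: tuple[float, float, float] = BAND_EDGES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def functional_mask(self) -> np.ndarray:
        return (self.labels == LABEL_NAA) | (self.labels == LABEL_HAA)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == lab))
            for name, lab in (
                ("LAA", LABEL_LAA),
                ("NAA", LABEL_NAA),
                ("HAA", LABEL_HAA),
                ("excluded", LABEL_EXCLUDED),
            )
        }


def segment_lungs(
    vnc_insp: ScalarVolume,
    threshold_hu: float = LUNG_THRESHOLD_HU,
    min_component_voxels: int | None = None,
) -> np.ndarray:
    """Binary lung mask from an inspiration VNC volume."""
    hu = np.asarray(vnc_insp.data, dtype=np.float64)
    candidate = hu < threshold_hu
    if not np.any(candidate):
        raise SegmentationError("no voxels below the lung threshold")

    labels, n = ndimage.label(candidate)
    if n == 0:
        raise SegmentationError("no connected air component found")
    # drop components touching the volume border (outside-body air)
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels |= set(np.unique(face[face > 0]).tolist())
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    keep = [lab for lab in order if lab not in border_labels][:2]
    if min_component_voxels is None:
        min_component_voxels = max(32, int(0.0005 * hu.size))
    keep = [lab for lab in keep if sizes[lab - 1] >= min_component_voxels]
    if not keep:
        raise SegmentationError("no intrathoracic lung-like component found")
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def classify_bands(vnc_insp: ScalarVolume, lung_mask: np.ndarray) -> BandLabelMap:
    """Classify lung voxels into LAA / NAA / HAA / excluded HU bands."""
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != vnc_insp.data.shape:
        raise GeometryError("lung mask shape does not match the VNC volume")
    hu = np.asarray(vnc_insp.data, dtype=np.float64)
    lo, mid, hi = BAND_EDGES
    labels = np.zeros(hu.shape, dtype=np.int16)
    labels[lung_mask & (hu < lo)] = LABEL_LAA
    labels[lung_mask & (hu >= lo) & (hu < mid)] = LABEL_NAA
    labels[lung_mask & (hu >= mid) & (hu < hi)] = LABEL_HAA
    labels[lung_mask & (hu >= hi)] = LABEL_EXCLUDED
    return BandLabelMap(labels, vnc_insp.spacing, vnc_insp.origin)


def exclude_vessels_by_pbv(
    bands: BandLabelMap,
    pbv: ScalarVolume,
    threshold: float,
    dilation_voxels: int = 1,
) -> BandLabelMap:
    """Optional extra vessel exclusion: relabel high-iodine voxels as excluded.

    Off by default in the pipeline; catches contrast-filled small vessels
    whose partial-volume HU falls below -250.
    """
    if pbv.data.shape != bands.labels.shape:
        raise GeometryError("PBV grid does not match the band map")
    vessel = np.asarray(pbv.data) > threshold
    if dilation_voxels > 0:
        vessel = ndimage.binary_dilation(vessel, iterations=dilation_voxels)
    labels = bands.labels.copy()
    labels[vessel & (labels > 0)] = LABEL_EXCLUDED
    return BandLabelMap(labels, bands.spacing, bands.origin, bands.band_edges)


def functional_fraction(bands: BandLabelMap) -> float:
    """(NAA + HAA voxels) / all lung voxels."""
    n_lung = int(np.count_nonzero(bands.labels > 0))
    if n_lung == 0:
        raise EmptyRegionError("lung mask is empty")
    return float(np.count_nonzero(bands.functional_mask) / n_lung)
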