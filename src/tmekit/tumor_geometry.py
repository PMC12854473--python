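"""Tumor-region geometry: labeling, nucleus assignment, class refinement,
and the vicinity ring.

The tumor mask lives at a coarser resolution than the nucleus frame; every
conversion between the two uses the package-wide convention
``mask_pixel = (floor(y / downsample), floor(x / downsample))``.

The refinement step encodes the tissue-context rule used to separate two
morphologically identical cell types: a nucleus classified as tumor that
falls outside every segmented tumor region is re-labelled non-neoplastic
epithelial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import (
    CLASS_EPITHELIAL,
    CLASS_TUMOR,
    SlideAnnotation,
    TumorMask,
)

__all__ = [
    "TumorRegionSet",
    "VicinityConfig",
    "label_tumor_regions",
    "assign_nuclei_to_regions",
    "reclassify_epithelial",
    "compute_vicinity",
]

logger = logging.getLogger(__name__)

# 8-connectivity: diagonal mask pixels belong to the same tumor region.
_STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass
class TumorRegionSet:
    """Connected tumor regions of one slide.

    label_raster holds 0 for background and k >= 1 for region k, at mask
    resolution.  Bounding boxes are stored in nucleus-frame pixels as
    (x_min, y_min, l_t, w_t) where l_t is the box extent along x and w_t
    along y — the side lengths that parameterize the expanding-rectangle
    search.
    """

    label_raster: np.ndarray
    downsample: int
    bounding_boxes: dict[int, tuple[float, float, float, float]] = field(default_factory=dict)
    areas_px: dict[int, int] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.bounding_boxes)

    def region_at(self, x: float, y: float) -> int:
        """Region id at nucleus-frame point (x, y); 0 off-raster or background."""
        row = int(np.floor(y / self.downsample))
        col = int(np.floor(x / self.downsample))
        h, w = self.label_raster.shape
        if not (0 <= row < h and 0 <= col < w):
            return 0
        return int(self.label_raster[row, col])

    def area_mm2(self, region_id: int, mpp: float) -> float:
        """Region area in mm^2 given the nucleus-frame scale in microns/pixel."""
        px_mm = mpp * self.downsample / 1000.0
        return self.areas_px[region_id] * px_mm * px_mm

    def total_area_mm2(self, mpp: float) -> float:
        px_mm = mpp * self.downsample / 1000.0
        return sum(self.areas_px.values()) * px_mm * px_mm


@dataclass
class VicinityConfig:
    """Width of the peritumoral band, physically anchored (default 1 mm)."""

    width_mm: float = 1.0
    mpp: float = 0.5
    downsample: int = 1

    def __post_init__(self) -> None:
        if self.width_mm <= 0:
            raise ValueError(f"width_mm must be positive, got {self.width_mm}")


def label_tumor_regions(mask: TumorMask) -> TumorRegionSet:
    """Connected-component labeling of the tumor mask (8-connectivity).

    Bounding boxes are tight around each region and reported in nucleus-frame
    pixels (mask coordinates scaled by the downsample factor).
    """
    labels, n = ndimage.label(mask.raster, structure=_STRUCTURE_8)
    boxes: dict[int, tuple[float, float, float, float]] = {}
    areas: dict[int, int] = {}
    ds = mask.downsample
    slices = ndimage.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        rows, cols = sl
        x_min = cols.start * ds
        y_min = rows.start * ds
        l_t = (cols.stop - cols.start) * ds  # extent along x
        w_t = (rows.stop - rows.start) * ds  # extent along y
        boxes[k] = (float(x_min), float(y_min), float(l_t), float(w_t))
        areas[k] = int((labels == k).sum())
    return TumorRegionSet(
        label_raster=labels.astype(np.int32),
        downsample=ds,
        bounding_boxes=boxes,
        areas_px=areas,
    )


def assign_nuclei_to_regions(
    annotation: SlideAnnotation, regions: TumorRegionSet
) -> SlideAnnotation:
    """Set each nucleus's tumor_region_id from the label at its centroid.

    Membership is decided at the centroid only.  Centroids that map outside
    the label raster count as background; their number is logged.
    """
    out = annotation.copy()
    n_off = 0
    h, w = regions.label_raster.shape
    ds = regions.downsample
    for nuc in out.nuclei:
        x, y = nuc.centroid
        row = int(np.floor(y / ds))
        col = int(np.floor(x / ds))
        if not (0 <= row < h and 0 <= col < w):
            nuc.tumor_region_id = 0
            n_off += 1
        else:
            nuc.tumor_region_id = int(regions.label_raster[row, col])
    if n_off:
        logger.info(
            "assign_nuclei_to_regions: %d centroids fell outside the mask raster "
            "and were treated as background",
            n_off,
        )
    return out


def reclassify_epithelial(
    annotation: SlideAnnotation, regions: TumorRegionSet
) -> tuple[SlideAnnotation, int]:
    """Relabel tumor-class nuclei outside every tumor region as epithelial.

    Returns the refined annotation and the number of changed records.  All
    other classes are untouched, so class counts 1-4 are conserved and
    n_tumor_before == n_tumor_after + n_reclassified.  Idempotent.
    """
    if any(n.tumor_region_id is None for n in annotation.nuclei):
        raise ValueError(
            "tumor_region_id not assigned; run assign_nuclei_to_regions first"
        )
    out = annotation.copy()
    changed = 0
    for nuc in out.nuclei:
        if nuc.class_label == CLASS_TUMOR and nuc.tumor_region_id == 0:
            nuc.class_label = CLASS_EPITHELIAL
            changed += 1
    return out, changed


def compute_vicinity(regions: TumorRegionSet, cfg: VicinityConfig) -> np.ndarray:
    """Binary raster (mask resolution) of the ring around the tumor.

    The ring is the Euclidean dilation of the tumor union by
    ``round(width_mm * 1000 / (mpp * downsample))`` mask pixels, minus the
    tumor itself, computed with a distance transform so the band is isotropic.
    """
    px_um = cfg.mpp * cfg.downsample
    radius = int(round(cfg.width_mm * 1000.0 / px_um))
    if cfg.width_mm * 1000.0 < px_um:
        raise ValueError(
            f"vicinity width {cfg.width_mm} mm is thinner than one mask pixel "
            f"({px_um} um)"
        )
    tumor = regions.label_raster > 0
    if not tumor.any():
        return np.zeros_like(tumor, dtype=np.uint8)
    dist = ndimage.distance_transform_edt(~tumor)
    ring = (dist > 0) & (dist <= radius)
    return ring.astype(np.uint8)
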