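"""Compute the slide-level feature encoding.

Given a refined annotation (region ids assigned, tumor-class nuclei outside
tumor regions relabelled epithelial) and the labelled tumor regions, this
module evaluates every entry of the feature registry and returns one
:class:`~tmekit.io_formats.FeatureVector`.

Zone membership of a nucleus is decided at its centroid: ``tumor`` when its
tumor_region_id is positive, otherwise ``vicinity`` when the centroid falls
on the 1 mm ring around the tumor, otherwise ``outside``.  The three zones
are disjoint and partition the slide; ``whole`` aggregates all of them.

Count ratios use the smoothed log ratio

    eta(n_A, n_B) = (ln n_A + eps) / (ln n_B + eps),   eps = 1e-3,

which tempers the influence of extreme abundance differences compared to a
raw count quotient.  eta is undefined (missing) when either count is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, FeatureVector, SlideAnnotation, TumorMask
from .registry import FeatureRegistry, build_default_registry
from .spatial_metrics import DistanceQuery, SearchConfig, average_closest_distance
from .tumor_geometry import (
    TumorRegionSet,
    VicinityConfig,
    assign_nuclei_to_regions,
    compute_vicinity,
    label_tumor_regions,
    reclassify_epithelial,
)

__all__ = [
    "RatioSpec",
    "smoothed_log_ratio",
    "class_fraction",
    "cell_density",
    "compute_all_features",
    "encode_slide",
]

_ZONES = ("whole", "tumor", "vicinity", "outside")


@dataclass
class RatioSpec:
    """Smoothing parameter of the log ratio (natural log, eps outside it)."""

    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


def smoothed_log_ratio(n_a: int, n_b: int, spec: RatioSpec | None = None) -> float:
    """eta(n_A, n_B) = (ln n_A + eps) / (ln n_B + eps); missing if a count is 0."""
    spec = spec or RatioSpec()
    if n_a < 0 or n_b < 0:
        raise ValueError(f"counts must be non-negative, got {n_a}, {n_b}")
    if n_a == 0 or n_b == 0:
        return MISSING
    return (math.log(n_a) + spec.epsilon) / (math.log(n_b) + spec.epsilon)


class _ZoneIndex:
    """Per-slide zone bookkeeping: nucleus zones, counts, and zone areas."""

    def __init__(
        self,
        annotation: SlideAnnotation,
        regions: TumorRegionSet,
        vicinity_width_mm: float = 1.0,
    ) -> None:
        if any(n.tumor_region_id is None for n in annotation.nuclei):
            raise ValueError(
                "tumor_region_id not assigned; run assign_nuclei_to_regions first"
            )
        ds = regions.downsample
        ring = compute_vicinity(
            regions,
            VicinityConfig(width_mm=vicinity_width_mm, mpp=annotation.mpp, downsample=ds),
        )
        h, w = regions.label_raster.shape

        self.counts: dict[tuple[int, str], int] = {}
        self.zone_totals: dict[str, int] = {z: 0 for z in _ZONES}
        for n in annotation.nuclei:
            if n.tumor_region_id and n.tumor_region_id > 0:
                zone = "tumor"
            else:
                row = int(np.floor(n.centroid[1] / ds))
                col = int(np.floor(n.centroid[0] / ds))
                on_ring = 0 <= row < h and 0 <= col < w and ring[row, col]
                zone = "vicinity" if on_ring else "outside"
            for z in ("whole", zone):
                self.counts[(n.class_label, z)] = self.counts.get((n.class_label, z), 0) + 1
                self.zone_totals[z] += 1

        px_mm2 = (annotation.mpp * ds / 1000.0) ** 2
        iw, ih = annotation.image_size
        whole_mm2 = iw * ih * (annotation.mpp / 1000.0) ** 2
        tumor_mm2 = float((regions.label_raster > 0).sum()) * px_mm2
        vicinity_mm2 = float(ring.sum()) * px_mm2
        self.zone_area_mm2 = {
            "whole": whole_mm2,
            "tumor": tumor_mm2,
            "vicinity": vicinity_mm2,
            "outside": max(whole_mm2 - tumor_mm2 - vicinity_mm2, 0.0),
        }

    def count(self, cls: int, zone: str) -> int:
        return self.counts.get((cls, zone), 0)


def class_fraction(
    annotation: SlideAnnotation,
    zone: str,
    class_label: int,
    regions: TumorRegionSet,
    *,
    vicinity_width_mm: float = 1.0,
) -> float:
    """Share of ``class_label`` among all cells of ``zone``; missing if empty."""
    if zone not in _ZONES:
        raise ValueError(f"unknown zone {zone!r}; expected one of {_ZONES}")
    idx = _ZoneIndex(annotation, regions, vicinity_width_mm)
    total = idx.zone_totals[zone]
    if total == 0:
        return MISSING
    return idx.count(class_label, zone) / total


def cell_density(
    annotation: SlideAnnotation,
    zone: str,
    class_label: int,
    regions: TumorRegionSet,
    mpp: float | None = None,
    *,
    vicinity_width_mm: float = 1.0,
) -> float:
    """Cells of ``class_label`` per mm^2 of ``zone``; missing if zero area."""
    if zone not in _ZONES:
        raise ValueError(f"unknown zone {zone!r}; expected one of {_ZONES}")
    if mpp is not None and mpp != annotation.mpp:
        annotation = annotation.copy()
        annotation.mpp = mpp
    if annotation.mpp <= 0:
        raise ValueError("mpp must be set and positive")
    idx = _ZoneIndex(annotation, regions, vicinity_width_mm)
    area = idx.zone_area_mm2[zone]
    if area <= 0:
        return MISSING
    return idx.count(class_label, zone) / area


def compute_all_features(
    annotation: SlideAnnotation,
    regions: TumorRegionSet,
    registry: FeatureRegistry | None = None,
    *,
    vicinity_width_mm: float = 1.0,
    search: SearchConfig | None = None,
    ratio_spec: RatioSpec | None = None,
) -> FeatureVector:
    """Evaluate every registry entry for one slide.

    Deterministic given its inputs and invariant under nucleus reordering.
    Features whose zone holds no cells (or no area) are missing, as are
    distances without any usable source/target pair.
    """
    registry = registry or build_default_registry()
    search = search or SearchConfig()
    ratio_spec = ratio_spec or RatioSpec()
    idx = _ZoneIndex(annotation, regions, vicinity_width_mm)

    # distance features share the per-pair averages
    distance_cache: dict[tuple[int, int], float] = {}

    values: dict[str, float] = {}
    for spec in registry:
        if spec.family == "fraction":
            total = idx.zone_totals[spec.zone]
            values[spec.name] = (
                idx.count(spec.source_class, spec.zone) / total if total else MISSING
            )
        elif spec.family == "density":
            area = idx.zone_area_mm2[spec.zone]
            values[spec.name] = (
                idx.count(spec.source_class, spec.zone) / area if area > 0 else MISSING
            )
        elif spec.family == "repartition":
            class_total = idx.count(spec.source_class, "whole")
            values[spec.name] = (
                idx.count(spec.source_class, spec.zone) / class_total
                if class_total
                else MISSING
            )
        elif spec.family == "ratio":
            zone_b = spec.target_zone or spec.zone
            values[spec.name] = smoothed_log_ratio(
                idx.count(spec.source_class, spec.zone),
                idx.count(spec.target_class, zone_b),
                ratio_spec,
            )
        elif spec.family == "distance":
            pair = (spec.source_class, spec.target_class)
            if pair not in distance_cache:
                res = average_closest_distance(
                    annotation, regions, DistanceQuery(*pair), search
                )
                distance_cache[pair] = MISSING if res.missing else res.mean_um
            values[spec.name] = distance_cache[pair]
        else:  # pragma: no cover - registry validation prevents this
            raise ValueError(f"unknown feature family {spec.family!r}")

    return FeatureVector(sample_id=annotation.sample_id, values=values)


def encode_slide(
    annotation: SlideAnnotation,
    mask: TumorMask,
    registry: FeatureRegistry | None = None,
    *,
    vicinity_width_mm: float = 1.0,
    search: SearchConfig | None = None,
) -> FeatureVector:
    """Full per-slide pipeline: label regions, assign nuclei, refine classes,
    then compute the feature vector.  One call per slide."""
    regions = label_tumor_regions(mask)
    assigned = assign_nuclei_to_regions(annotation, regions)
    refined, _ = reclassify_epithelial(assigned, regions)
    return compute_all_features(
        refined,
        regions,
        registry,
        vicinity_width_mm=vicinity_width_mm,
        search=search,
    )
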