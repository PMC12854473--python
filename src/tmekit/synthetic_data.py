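"""Synthetic slides, cohorts, and the rectangle-search Monte Carlo.

The slide generator emulates the *output* of the two upstream segmentation
models, not the pixels they see: smoothly deformed tumor blobs rasterized
into a binary mask, and nuclei placed by independent Poisson sampling with
zone-specific intensities (cells per mm^2) for each of the five raw classes.
Nuclei are placed uniformly within their zone, so every ground-truth count
is exact by construction and the emitted files round-trip through
:mod:`tmekit.io_formats`.

The cohort generator draws two patient groups (responder / non-responder)
whose zone intensities differ for a small set of planted effects, with
multiplicative log-normal between-patient heterogeneity on every intensity.
Defaults mirror a 45-patient immunotherapy cohort (28 responders, 17
non-responders) with four planted effects: more lymphocytes inside and
around the tumor in responders, more granulocytes around the tumor in
non-responders, and fewer intratumoral plasma cells in non-responders
(which stretches the granulocyte-to-plasma closest-cell distance).

``mc_overestimation_probability`` quantifies how often a centered-square
search returns a non-nearest point: with N points drawn uniformly in the
circle in which the square (full side 2*r1) is inscribed, the error event
requires at least one point inside the square while the globally nearest
point lies outside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .io_formats import (
    CohortTable,
    NucleusRecord,
    SlideAnnotation,
    TumorMask,
    write_cohort_csv,
    write_nucleus_json,
    write_tumor_mask,
)
from .tumor_geometry import VicinityConfig, compute_vicinity, label_tumor_regions

__all__ = [
    "SlideSimConfig",
    "CohortSimConfig",
    "FeatureCohortSimConfig",
    "OverestimationSimConfig",
    "simulate_slide",
    "simulate_cohort",
    "simulate_feature_cohort",
    "mc_overestimation_probability",
    "DEFAULT_INTENSITIES",
]

_ZONES = ("tumor", "vicinity", "outside")

#: Baseline zone intensities in cells per mm^2, chosen to resemble a
#: moderately inflamed carcinoma: tumor cells dominate their regions, the
#: peritumoral band carries the immune infiltrate, and sparse stroma with
#: some non-neoplastic epithelium (emitted as raw tumor-class calls that the
#: refinement relabels) fills the rest of the slide.
DEFAULT_INTENSITIES: dict[str, dict[int, float]] = {
    "tumor": {1: 60.0, 2: 250.0, 3: 60.0, 4: 120.0, 5: 700.0},
    "vicinity": {1: 100.0, 2: 200.0, 3: 70.0, 4: 180.0, 5: 15.0},
    "outside": {1: 25.0, 2: 50.0, 3: 20.0, 4: 140.0, 5: 35.0},
}


@dataclass
class SlideSimConfig:
    """Geometry and intensities of one synthetic slide."""

    image_size: tuple[int, int] = (3072, 3072)  # nucleus-frame pixels (w, h)
    mpp: float = 1.0
    downsample: int = 8
    n_blobs: int = 2
    blob_radius_mm: float = 0.35
    blob_smoothness: float = 0.15  # relative amplitude of boundary harmonics
    vicinity_width_mm: float = 1.0
    intensities: dict[str, dict[int, float]] = field(
        default_factory=lambda: {z: dict(v) for z, v in DEFAULT_INTENSITIES.items()}
    )
    #: Pairwise inhibition, (zone, avoided_class, anchor_class) -> minimum
    #: distance in microns: cells of the avoided class are placed uniformly
    #: conditional on keeping at least that distance from every anchor-class
    #: cell of the zone (a hard-core marked point-process interaction).
    #: Counts are unaffected; only positions are.
    repulsion: dict[tuple[str, int, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w % self.downsample or h % self.downsample:
            raise ValueError("image_size must be divisible by downsample")
        for zone, per_class in self.intensities.items():
            if zone not in _ZONES:
                raise ValueError(f"unknown zone {zone!r}")
            for cls, lam in per_class.items():
                if lam < 0:
                    raise ValueError(f"negative intensity for class {cls} in {zone}")
        for (zone, avoided, anchor), radius in self.repulsion.items():
            if zone not in _ZONES:
                raise ValueError(f"repulsion references unknown zone {zone!r}")
            if radius < 0:
                raise ValueError("repulsion radius must be non-negative")
            if anchor >= avoided:
                raise ValueError(
                    "repulsion anchor class must be placed before the avoided "
                    f"class (anchor code < avoided code), got {(zone, avoided, anchor)}"
                )


def _blob_raster(cfg: SlideSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterize smoothly deformed tumor blobs at mask resolution."""
    w, h = cfg.image_size
    ds = cfg.downsample
    wm, hm = w // ds, h // ds
    raster = np.zeros((hm, wm), dtype=np.uint8)
    r_px = cfg.blob_radius_mm * 1000.0 / (cfg.mpp * ds)
    margin = r_px * (1.0 + 3 * cfg.blob_smoothness) + 1
    if 2 * margin >= min(wm, hm):
        raise ValueError("blobs do not fit inside the image; enlarge image_size")
    theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    for _ in range(cfg.n_blobs):
        cx = rng.uniform(margin, wm - margin)
        cy = rng.uniform(margin, hm - margin)
        r = np.full_like(theta, r_px)
        for harmonic in range(2, 6):
            amp = rng.normal(0.0, cfg.blob_smoothness / harmonic) * r_px
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(harmonic * theta + phase)
        r = np.clip(r, 0.2 * r_px, margin)
        rows, cols = draw_polygon(cy + r * np.sin(theta), cx + r * np.cos(theta), raster.shape)
        raster[rows, cols] = 1
    return raster


_OCT_ANGLES = np.linspace(0, 2 * np.pi, 8, endpoint=False)
_OCT_UNIT = np.stack([np.cos(_OCT_ANGLES), np.sin(_OCT_ANGLES)], axis=1)


def _octagons(xs: np.ndarray, ys: np.ndarray, radius: float):
    """Vectorized small octagon contours around many centroids.

    Contours may overhang the image edge slightly (as real segmentations do
    at tile borders); only centroids are bound to the image.
    """
    cx = xs[:, None] + radius * _OCT_UNIT[None, :, 0]
    cy = ys[:, None] + radius * _OCT_UNIT[None, :, 1]
    return [
        list(zip(cx[i].tolist(), cy[i].tolist()))
        for i in range(xs.size)
    ]


def simulate_slide(
    cfg: SlideSimConfig,
) -> tuple[SlideAnnotation, TumorMask, dict]:
    """Generate one synthetic slide; fully reproducible from cfg.seed.

    Returns the annotation (raw classifier classes 1-5), the tumor mask, and
    a ground-truth record with exact per-class per-zone counts, blob areas,
    and the number of tumor-class nuclei placed outside tumor regions (those
    the refinement will relabel epithelial).
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.image_size
    ds = cfg.downsample
    raster = _blob_raster(cfg, rng) if cfg.n_blobs > 0 else np.zeros(
        (h // ds, w // ds), dtype=np.uint8
    )
    mask = TumorMask(raster=raster, downsample=ds)
    regions = label_tumor_regions(mask)

    tumor_zone = regions.label_raster > 0
    if tumor_zone.any():
        ring = compute_vicinity(
            regions,
            VicinityConfig(width_mm=cfg.vicinity_width_mm, mpp=cfg.mpp, downsample=ds),
        ).astype(bool)
    else:
        ring = np.zeros_like(tumor_zone, dtype=bool)
    zone_masks = {
        "tumor": tumor_zone,
        "vicinity": ring,
        "outside": ~tumor_zone & ~ring,
    }
    if not tumor_zone.any():
        tumor_lams = cfg.intensities.get("tumor", {})
        if any(v > 0 for v in tumor_lams.values()):
            raise ValueError(
                "requested tumor-zone intensities > 0 but the slide has no tumor area"
            )

    px_mm2 = (cfg.mpp * ds / 1000.0) ** 2
    nuclei: list[NucleusRecord] = []
    counts: dict[str, dict[int, int]] = {z: {} for z in _ZONES}
    next_id = 1
    for zone in _ZONES:
        zmask = zone_masks[zone]
        pix_rows, pix_cols = np.nonzero(zmask)
        area_mm2 = pix_rows.size * px_mm2
        placed: dict[int, np.ndarray] = {}  # class -> (n, 2) coords in this zone
        for cls in sorted(cfg.intensities.get(zone, {})):
            lam = cfg.intensities[zone][cls] * area_mm2
            n = int(rng.poisson(lam)) if lam > 0 else 0
            counts[zone][cls] = n
            if n == 0:
                placed[cls] = np.empty((0, 2))
                continue

            def _draw(m: int) -> tuple[np.ndarray, np.ndarray]:
                pick = rng.integers(0, pix_rows.size, size=m)
                return (
                    pix_cols[pick] * ds + rng.uniform(0, ds, size=m),
                    pix_rows[pick] * ds + rng.uniform(0, ds, size=m),
                )

            xs, ys = _draw(n)
            anchor_key = next(
                (k for k in cfg.repulsion if k[0] == zone and k[1] == cls), None
            )
            if anchor_key is not None and cfg.repulsion[anchor_key] > 0:
                anchors = placed.get(anchor_key[2], np.empty((0, 2)))
                if anchors.size:
                    r_px = cfg.repulsion[anchor_key] / cfg.mpp
                    # rejection-resample until clear of every anchor disk;
                    # bounded rounds guarantee termination on dense anchors
                    for _ in range(100):
                        d2 = (
                            (xs[:, None] - anchors[None, :, 0]) ** 2
                            + (ys[:, None] - anchors[None, :, 1]) ** 2
                        ).min(axis=1)
                        bad = d2 < r_px * r_px
                        if not bad.any():
                            break
                        nx, ny = _draw(int(bad.sum()))
                        xs[bad], ys[bad] = nx, ny
            placed[cls] = np.stack([xs, ys], axis=1)
            contours = _octagons(xs, ys, 2.5)
            for x, y, contour in zip(xs.tolist(), ys.tolist(), contours):
                nuclei.append(
                    NucleusRecord(
                        instance_id=next_id,
                        centroid=(x, y),
                        contour=contour,
                        class_label=cls,
                    )
                )
                next_id += 1

    annotation = SlideAnnotation(
        nuclei=nuclei, mpp=cfg.mpp, image_size=cfg.image_size, sample_id=f"sim-{cfg.seed}"
    )
    ground_truth = {
        "counts": counts,
        "n_nuclei": len(nuclei),
        "tumor_pixel_count": int(tumor_zone.sum()),
        "vicinity_pixel_count": int(ring.sum()),
        "n_regions": regions.n_regions,
        "region_areas_px": dict(regions.areas_px),
        "expected_epithelial": counts["vicinity"].get(5, 0) + counts["outside"].get(5, 0),
        "seed": cfg.seed,
    }
    return annotation, mask, ground_truth


@dataclass
class CohortSimConfig:
    """Two-group cohort with planted group-conditional intensity effects.

    effects maps (class code, zone) to the (responder, non_responder)
    intensity in cells per mm^2, overriding the slide baseline for that cell;
    repulsion_effects maps a (zone, avoided class, anchor class) interaction
    to the (responder, non_responder) minimum distance in microns.  The
    default effects are moderate on purpose — no single feature separates
    the groups on its own; classification needs several of them:

    * responders carry more lymphocytes inside and around the tumor;
    * non-responders carry more granulocytes around the tumor (and mildly
      everywhere, as a diffuse systemic signature);
    * in non-responders, intratumoral plasma cells keep their distance from
      granulocytes (a spatial interaction that moves the closest-cell
      distance without changing any count);
    * a few weak effects in the distal tissue add the faint secondary
      signals real cohorts carry, so that classification accuracy keeps
      improving past the first handful of selected features.

    planted_features names the registry features those effects are designed
    to move.  patient_sigma is the independent log-normal between-patient
    scatter on each intensity; global_sigma is a shared per-patient
    cellularity factor multiplying all intensities of a slide (section
    thickness / staining variation), which is what makes relative features
    (fractions, ratios) cleaner group markers than absolute densities.
    """

    n_responders: int = 28
    n_non_responders: int = 17
    effects: dict[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: {
            (2, "tumor"): (340.0, 170.0),
            (2, "vicinity"): (270.0, 140.0),
            (1, "vicinity"): (85.0, 115.0),
            # weak diffuse signature in the distal tissue
            (3, "outside"): (24.0, 17.0),
            (4, "outside"): (130.0, 155.0),
        }
    )
    repulsion_effects: dict[tuple[str, int, int], tuple[float, float]] = field(
        default_factory=lambda: {("tumor", 3, 1): (0.0, 60.0)}
    )
    planted_features: tuple[str, ...] = (
        "fraction_lymphocyte_tumor",
        "fraction_lymphocyte_vicinity",
        "ratio_granulocyte_to_lymphocyte_vicinity",
        "dist_granulocyte_to_plasma_tumor_um",
    )
    patient_sigma: float = 0.25
    global_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 3 or self.n_non_responders < 3:
            raise ValueError("need at least 3 samples per group")
        for (cls, zone) in self.effects:
            if zone not in _ZONES or cls not in (1, 2, 3, 4, 5):
                raise ValueError(f"effect references unknown class/zone: ({cls}, {zone})")


def simulate_cohort(
    cfg: CohortSimConfig,
    slide_cfg: SlideSimConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate a labelled two-group cohort of synthetic slides.

    Returns a dict with the cohort table, the in-memory slides
    ``[(annotation, mask, slide_ground_truth), ...]`` in table order, and the
    cohort-level ground truth (planted feature names and effect table).
    When ``out_dir`` is given, annotation JSONs, mask PNGs and the cohort CSV
    are also written there.
    """
    slide_cfg = slide_cfg or SlideSimConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    slides = []
    groups = [("responder", "R", cfg.n_responders), ("non_responder", "N", cfg.n_non_responders)]
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for label, prefix, count in groups:
        for i in range(count):
            sample_id = f"{prefix}{i + 1:03d}"
            is_resp = label == "responder"
            intensities = {z: dict(v) for z, v in slide_cfg.intensities.items()}
            for (cls, zone), (resp_val, non_val) in cfg.effects.items():
                intensities[zone][cls] = resp_val if is_resp else non_val
            cellularity = float(rng.lognormal(mean=0.0, sigma=cfg.global_sigma))
            for zone in intensities:
                for cls in intensities[zone]:
                    intensities[zone][cls] *= cellularity * float(
                        rng.lognormal(mean=0.0, sigma=cfg.patient_sigma)
                    )
            repulsion = dict(slide_cfg.repulsion)
            for key, (resp_r, non_r) in cfg.repulsion_effects.items():
                repulsion[key] = resp_r if is_resp else non_r
            child_seed = int(rng.integers(0, 2**31 - 1))
            sample_cfg = dc_replace(
                slide_cfg, intensities=intensities, repulsion=repulsion, seed=child_seed
            )
            annotation, mask, gt = simulate_slide(sample_cfg)
            annotation.sample_id = sample_id
            ann_path = mask_path = ""
            if out_dir is not None:
                ann_path = str(out_dir / f"{sample_id}.json")
                mask_path = str(out_dir / f"{sample_id}_mask.png")
                write_nucleus_json(annotation, ann_path)
                write_tumor_mask(mask, mask_path)
            rows.append(
                {
                    "sample_id": sample_id,
                    "label": label,
                    "annotation_path": ann_path,
                    "mask_path": mask_path,
                }
            )
            slides.append((annotation, mask, gt))
    table = CohortTable(frame=pd.DataFrame(rows))
    if out_dir is not None:
        write_cohort_csv(table, out_dir / "cohort.csv")
    ground_truth = {
        "planted_features": list(cfg.planted_features),
        "effects": {f"{cls}:{zone}": list(v) for (cls, zone), v in cfg.effects.items()},
        "repulsion_effects": {
            f"{zone}:{avoided}:{anchor}": list(v)
            for (zone, avoided, anchor), v in cfg.repulsion_effects.items()
        },
        "n_responders": cfg.n_responders,
        "n_non_responders": cfg.n_non_responders,
        "seed": cfg.seed,
    }
    return {"cohort": table, "slides": slides, "ground_truth": ground_truth}


@dataclass
class FeatureCohortSimConfig:
    """Two-group cohort generated directly at the feature-table level.

    Unlike the slide-level cohort — where any intensity effect inevitably
    moves a whole family of correlated features — this generator controls
    exactly which feature columns carry group signal, which is the condition
    needed to test recovery of a known marker set by the selection protocol.

    Columns are the structure-analysis feature names (z-scored units).  Null
    features are drawn in correlated blocks (family structure of real
    encodings).  Each planted feature carries a shared responder shift
    (``base_shift``, in within-group SD units) plus a strong extra elevation
    in one quarter of the responders (``subtype_boost``): response arises
    through several immune configurations, so no single marker separates the
    groups and classification accuracy keeps improving as markers are added.
    A tail of weakly shifted features (``weak_shift``) mimics the diffuse
    secondary signature of real cohorts.
    """

    n_responders: int = 28
    n_non_responders: int = 17
    planted_features: tuple[str, ...] = (
        "fraction_lymphocyte_tumor",
        "fraction_lymphocyte_vicinity",
        "ratio_granulocyte_to_lymphocyte_vicinity",
        "dist_granulocyte_to_plasma_tumor_um",
    )
    base_shift: float = 1.6
    subtype_boost: float = 1.8
    weak_features: tuple[str, ...] = (
        "fraction_plasma_vicinity",
        "repartition_lymphocyte_outside",
        "density_granulocyte_outside",
        "fraction_stromal_tumor",
        "ratio_lymphocyte_to_plasma_tumor",
        "repartition_granulocyte_vicinity",
        "fraction_plasma_outside",
        "ratio_granulocyte_to_plasma_whole",
        "density_lymphocyte_vicinity",
        "fraction_granulocyte_whole",
    )
    weak_shift: float = 0.5
    null_block_size: int = 7
    null_block_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 4 or self.n_non_responders < 3:
            raise ValueError("cohort too small for the subtype structure")
        if not (0 <= self.null_block_corr < 1):
            raise ValueError("null_block_corr must be in [0, 1)")
        overlap = set(self.planted_features) & set(self.weak_features)
        if overlap:
            raise ValueError(f"features cannot be both planted and weak: {overlap}")


def simulate_feature_cohort(cfg: FeatureCohortSimConfig) -> dict:
    """Generate a labelled feature table with exactly known signal carriers.

    Returns ``{"features": DataFrame (samples x structure features),
    "labels": 0/1 array (1 = responder), "ground_truth": {...}}``.  All
    planted and weak feature names must exist in the default registry's
    structure subset.
    """
    from .registry import build_default_registry

    struct = build_default_registry().structure_names()
    for f in (*cfg.planted_features, *cfg.weak_features):
        if f not in struct:
            raise ValueError(f"effect references unknown structure feature {f!r}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_responders + cfg.n_non_responders
    labels = np.array([1] * cfg.n_responders + [0] * cfg.n_non_responders)

    rho = cfg.null_block_corr
    X = np.empty((n, len(struct)))
    shared = rng.normal(size=n)
    for j in range(len(struct)):
        if j % cfg.null_block_size == 0:
            shared = rng.normal(size=n)
        X[:, j] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal(size=n)
    table = pd.DataFrame(X, columns=struct)

    k = len(cfg.planted_features)
    subtype = rng.permutation(np.arange(cfg.n_responders) % k) if k else np.array([])
    for i, feat in enumerate(cfg.planted_features):
        shift = np.zeros(n)
        shift[: cfg.n_responders] = cfg.base_shift + cfg.subtype_boost * (subtype == i)
        table[feat] = rng.normal(size=n) + shift
    for feat in cfg.weak_features:
        table[feat] = rng.normal(size=n) + np.where(
            labels == 1, cfg.weak_shift / 2.0, -cfg.weak_shift / 2.0
        )

    sample_ids = [
        f"{'R' if lab else 'N'}{i + 1:03d}" for i, lab in enumerate(labels)
    ]
    table.index = pd.Index(sample_ids, name="sample_id")
    ground_truth = {
        "planted_features": list(cfg.planted_features),
        "weak_features": list(cfg.weak_features),
        "base_shift": cfg.base_shift,
        "subtype_boost": cfg.subtype_boost,
        "weak_shift": cfg.weak_shift,
        "seed": cfg.seed,
    }
    return {"features": table, "labels": labels, "ground_truth": ground_truth}


@dataclass
class OverestimationSimConfig:
    """Monte-Carlo setup for the square-search overestimation probability.

    The square has full side 2*r1 and is centered at the origin; sampling is
    uniform in the disk in which the square is inscribed (radius r1*sqrt(2)).
    The alternative reading with disk radius 2*r1 is exposed as
    geometry="wide".
    """

    n_points: int = 2
    replicates: int = 2_000_000
    seed: int = 0
    geometry: str = "inscribed"  # or "wide"
    #: True (default): probability conditional on the square capturing at
    #: least one point, i.e. the error rate of a search that stops at this
    #: square.  False: unconditional frequency of (capture AND error) draws.
    conditional: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.geometry not in ("inscribed", "wide"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def mc_overestimation_probability(
    cfg: OverestimationSimConfig, batch: int = 250_000
) -> tuple[float, float]:
    """Estimate the square-search overestimation probability and its SE.

    Per replicate, N points are drawn uniformly in the disk; the error event
    requires at least one point inside the square while the point globally
    nearest to the origin lies outside the square (a draw with no in-square
    point is not an error: the expanding search simply continues and finds
    the true minimum).

    By default the estimate is conditional on the square capturing at least
    one point — the error rate of a search that stops at this square.  With
    ``cfg.conditional=False`` the unconditional event frequency over all
    draws is returned.  Returns (p_hat, sqrt(p_hat (1 - p_hat) / n)) with n
    the relevant denominator.
    """
    if cfg.n_points >= 10 and cfg.replicates < 1_000_000:
        warnings.warn(
            "fewer than 1e6 replicates for N >= 10: the event is rare and the "
            "estimate will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    r1 = 1.0
    radius = r1 * np.sqrt(2.0) if cfg.geometry == "inscribed" else 2.0 * r1
    events = 0
    captures = 0
    done = 0
    while done < cfg.replicates:
        b = min(batch, cfg.replicates - done)
        r = radius * np.sqrt(rng.uniform(size=(b, cfg.n_points)))
        theta = rng.uniform(0, 2 * np.pi, size=(b, cfg.n_points))
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        inside = (np.abs(x) <= r1) & (np.abs(y) <= r1)
        nearest = np.argmin(x**2 + y**2, axis=1)
        nearest_inside = inside[np.arange(b), nearest]
        any_inside = inside.any(axis=1)
        captures += int(any_inside.sum())
        events += int(np.sum(any_inside & ~nearest_inside))
        done += b
    denom = captures if cfg.conditional else cfg.replicates
    if denom == 0:
        return 0.0, 0.0
    p = events / denom
    se = float(np.sqrt(p * (1.0 - p) / denom))
    return p, se
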