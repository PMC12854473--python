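"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* nucleus annotation JSON (HoVer-Net output dialect): a top-level mapping
  ``instance_id -> {"centroid": [x, y], "contour": [[x, y], ...], "type": int}``,
  optionally nested under a ``"nuc"`` key with sibling metadata keys;
* binary tumor-region masks as PNG or single-page TIFF rasters;
* flat feature-vector JSON files;
* cohort tables as CSV.

Coordinate convention throughout the package: ``x`` is the column, ``y`` the
row, origin at the top-left, 0-based, in pixel units of the full-resolution
nucleus frame.  A point ``(x, y)`` falls on mask pixel
``raster[floor(y / downsample), floor(x / downsample)]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CLASS_GRANULOCYTE",
    "CLASS_LYMPHOCYTE",
    "CLASS_PLASMA",
    "CLASS_STROMAL",
    "CLASS_TUMOR",
    "CLASS_EPITHELIAL",
    "CLASS_NAMES",
    "MISSING",
    "is_missing",
    "NucleusRecord",
    "SlideAnnotation",
    "TumorMask",
    "FeatureVector",
    "CohortTable",
    "read_nucleus_json",
    "write_nucleus_json",
    "read_tumor_mask",
    "write_tumor_mask",
    "read_feature_json",
    "write_feature_json",
    "read_cohort_csv",
    "AnnotationFormatError",
]

# Integer class codes of the nucleus classifier.  Codes 1-5 are produced
# upstream; code 6 (non-neoplastic epithelial) only exists after the
# tumor-mask refinement step.
CLASS_GRANULOCYTE = 1
CLASS_LYMPHOCYTE = 2
CLASS_PLASMA = 3
CLASS_STROMAL = 4
CLASS_TUMOR = 5
CLASS_EPITHELIAL = 6

CLASS_NAMES: dict[int, str] = {
    CLASS_GRANULOCYTE: "granulocyte",
    CLASS_LYMPHOCYTE: "lymphocyte",
    CLASS_PLASMA: "plasma",
    CLASS_STROMAL: "stromal",
    CLASS_TUMOR: "tumor",
    CLASS_EPITHELIAL: "epithelial",
}

RAW_CLASS_CODES = frozenset({1, 2, 3, 4, 5})
REFINED_CLASS_CODES = frozenset({1, 2, 3, 4, 5, 6})

#: Sentinel for an undefined feature value (empty zone, no target cells, ...).
#: Serialized as JSON ``null``.
MISSING: float = float("nan")


def is_missing(value: float) -> bool:
    """True when ``value`` is the missing-feature sentinel."""
    return value is None or (isinstance(value, float) and math.isnan(value))


class AnnotationFormatError(ValueError):
    """Raised when an annotation file violates the expected dialect."""


@dataclass
class NucleusRecord:
    """One segmented nucleus.

    ``tumor_region_id`` is ``None`` until region assignment has run; after
    assignment it is 0 for nuclei outside every tumor region and the positive
    region label otherwise.
    """

    instance_id: int
    centroid: tuple[float, float]
    contour: list[tuple[float, float]]
    class_label: int
    tumor_region_id: int | None = None

    def __post_init__(self) -> None:
        if self.instance_id <= 0:
            raise ValueError(f"instance_id must be positive, got {self.instance_id}")
        if len(self.contour) < 3:
            raise ValueError(
                f"nucleus {self.instance_id}: contour needs >= 3 vertices, "
                f"got {len(self.contour)}"
            )
        if self.class_label not in REFINED_CLASS_CODES:
            raise ValueError(
                f"nucleus {self.instance_id}: class_label {self.class_label} "
                f"not in {sorted(REFINED_CLASS_CODES)}"
            )
        x, y = self.centroid
        if not (math.isfinite(x) and math.isfinite(y)):
            raise AnnotationFormatError(
                f"nucleus {self.instance_id}: non-finite centroid {self.centroid}"
            )
        xs = [p[0] for p in self.contour]
        ys = [p[1] for p in self.contour]
        if not (min(xs) - 1e-6 <= x <= max(xs) + 1e-6 and min(ys) - 1e-6 <= y <= max(ys) + 1e-6):
            raise ValueError(
                f"nucleus {self.instance_id}: centroid outside contour bounding box"
            )


@dataclass
class SlideAnnotation:
    """All nuclei of one slide plus the slide-level metadata.

    mpp is the physical scale (microns per pixel) of the nucleus coordinate
    frame; image_size is (width, height) in the same frame.
    """

    nuclei: list[NucleusRecord]
    mpp: float
    image_size: tuple[int, int]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        ids = [n.instance_id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError("instance_ids are not unique")
        w, h = self.image_size
        for n in self.nuclei:
            x, y = n.centroid
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"nucleus {n.instance_id}: centroid {n.centroid} outside "
                    f"image bounds {self.image_size}"
                )

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for n in self.nuclei:
            counts[n.class_label] = counts.get(n.class_label, 0) + 1
        return counts

    def copy(self) -> "SlideAnnotation":
        return SlideAnnotation(
            nuclei=[replace(n) for n in self.nuclei],
            mpp=self.mpp,
            image_size=self.image_size,
            sample_id=self.sample_id,
        )


@dataclass
class TumorMask:
    """Binary tumor raster at a coarser resolution than the nucleus frame.

    ``downsample`` maps one mask pixel to ``downsample`` nucleus-frame pixels
    along each axis.
    """

    raster: np.ndarray
    downsample: int

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError(f"downsample must be >= 1, got {self.downsample}")
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        self.raster = (self.raster != 0).astype(np.uint8)

    @property
    def tumor_pixel_count(self) -> int:
        return int(self.raster.sum())


@dataclass
class FeatureVector:
    """One slide's computed feature values, keyed and ordered by the registry."""

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sample_id, dtype=float)


@dataclass
class CohortTable:
    """Sample sheet of a two-group cohort (responder / non_responder)."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "label", "annotation_path", "mask_path")
    LABELS = ("responder", "non_responder")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("cohort table has duplicate sample_ids")
        bad = set(self.frame["label"]) - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown cohort labels {sorted(bad)}; expected {self.LABELS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def binary_labels(self) -> np.ndarray:
        """1 for responder, 0 for non_responder."""
        return (self.frame["label"] == "responder").to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# nucleus annotation JSON


def read_nucleus_json(
    path: str | Path,
    *,
    allow_refined: bool = True,
    mpp: float | None = None,
) -> SlideAnnotation:
    """Parse a HoVer-Net-style nucleus annotation file.

    The file is a JSON object mapping instance id to a record with
    ``centroid``, ``contour`` and ``type`` fields, either at the top level or
    under a ``"nuc"`` key.  ``mpp`` and ``image_size`` are read from the file
    when present; an explicit ``mpp`` argument overrides the file.

    With ``allow_refined=False`` only the raw classifier codes 1-5 are
    accepted; the default also accepts the post-refinement epithelial code 6.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict):
        raise AnnotationFormatError(f"{path}: top level must be a JSON object")

    meta: dict = {}
    if "nuc" in payload:
        instances = payload["nuc"]
        meta = {k: v for k, v in payload.items() if k != "nuc"}
    else:
        instances = {k: v for k, v in payload.items() if isinstance(v, dict) and "centroid" in v}
        meta = {k: v for k, v in payload.items() if k not in instances}

    allowed = REFINED_CLASS_CODES if allow_refined else RAW_CLASS_CODES
    records: list[NucleusRecord] = []
    for key, inst in instances.items():
        if not isinstance(inst, dict):
            raise AnnotationFormatError(f"{path}: instance {key!r} is not an object")
        for fld in ("centroid", "contour", "type"):
            if fld not in inst:
                raise AnnotationFormatError(f"{path}: instance {key!r} lacks {fld!r}")
        cx, cy = inst["centroid"]
        if cx is None or cy is None or not (math.isfinite(float(cx)) and math.isfinite(float(cy))):
            raise AnnotationFormatError(f"{path}: instance {key!r} has missing/NaN centroid")
        cls = int(inst["type"])
        if cls not in allowed:
            raise AnnotationFormatError(
                f"{path}: instance {key!r} has class code {cls}; "
                f"allowed codes are {sorted(allowed)}"
            )
        contour = [(float(x), float(y)) for x, y in inst["contour"]]
        rid = inst.get("tumor_region_id")
        records.append(
            NucleusRecord(
                instance_id=int(key),
                centroid=(float(cx), float(cy)),
                contour=contour,
                class_label=cls,
                tumor_region_id=None if rid is None else int(rid),
            )
        )

    file_mpp = meta.get("mpp")
    eff_mpp = mpp if mpp is not None else (float(file_mpp) if file_mpp else 1.0)
    image_size = meta.get("image_size")
    if image_size is None:
        # Fall back to the tightest integer box containing every centroid.
        if records:
            w = int(math.ceil(max(n.centroid[0] for n in records))) + 1
            h = int(math.ceil(max(n.centroid[1] for n in records))) + 1
        else:
            w = h = 1
        image_size = (w, h)
    return SlideAnnotation(
        nuclei=sorted(records, key=lambda n: n.instance_id),
        mpp=eff_mpp,
        image_size=(int(image_size[0]), int(image_size[1])),
        sample_id=str(meta.get("sample_id", path.stem)),
    )


def write_nucleus_json(annotation: SlideAnnotation, path: str | Path) -> None:
    """Write an annotation back to the nucleus JSON dialect (re-readable)."""
    payload: dict = {
        "mpp": annotation.mpp,
        "image_size": list(annotation.image_size),
        "sample_id": annotation.sample_id,
        "nuc": {},
    }
    for n in annotation.nuclei:
        rec = {
            "centroid": list(n.centroid),
            "contour": [list(p) for p in n.contour],
            "type": n.class_label,
        }
        if n.tumor_region_id is not None:
            rec["tumor_region_id"] = n.tumor_region_id
        payload["nuc"][str(n.instance_id)] = rec
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# tumor mask rasters


def read_tumor_mask(path: str | Path, downsample: int) -> TumorMask:
    """Read a binary tumor mask from a PNG or single-page TIFF.

    Any nonzero pixel counts as tumor.  Multi-channel images are accepted only
    when all channels agree (e.g. a gray image saved as RGB).
    """
    if downsample < 1:
        raise ValueError(f"downsample must be >= 1, got {downsample}")
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop a fully-opaque alpha channel
            img = img[:, :, :3]
        if not (img == img[:, :, :1]).all():
            raise ValueError(f"{path}: channels disagree; mask must be single-channel")
        img = img[:, :, 0]
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {img.shape}")
    return TumorMask(raster=img, downsample=int(downsample))


def write_tumor_mask(mask: TumorMask, path: str | Path) -> None:
    iio.imwrite(path, (mask.raster * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# feature-vector JSON


def write_feature_json(fv: FeatureVector, path: str | Path, *, registry=None) -> None:
    """Serialize a feature vector as a flat JSON object in registry order.

    Missing values become JSON ``null``.  When a registry is given, the
    vector's key set must match it exactly.
    """
    if registry is not None:
        names = list(registry.names)
        if list(fv.values.keys()) != names:
            unknown = set(fv.values) - set(names)
            if unknown:
                raise ValueError(f"values for unknown feature names: {sorted(unknown)[:5]}")
            raise ValueError("feature vector keys do not match registry order")
    flat = {
        "sample_id": fv.sample_id,
        "features": {
            k: (None if is_missing(v) else float(v)) for k, v in fv.values.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(flat, fh)


def read_feature_json(path: str | Path) -> FeatureVector:
    with open(path) as fh:
        flat = json.load(fh)
    values = {k: (MISSING if v is None else float(v)) for k, v in flat["features"].items()}
    return FeatureVector(sample_id=flat.get("sample_id", Path(path).stem), values=values)


# ---------------------------------------------------------------------------
# cohort CSV


def read_cohort_csv(path: str | Path) -> CohortTable:
    frame = pd.read_csv(path, dtype=str)
    return CohortTable(frame=frame)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)
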