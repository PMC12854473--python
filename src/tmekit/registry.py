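"""The versioned catalogue of the 317 slide-level features.

The registry is a single, ordered enumeration over feature families so the
whole encoding is reproducible and name-stable.  Five families exist:

``fraction``
    share of a cell class among all cells of a zone;
``density``
    cells of a class per mm^2 of a zone;
``repartition``
    how one class distributes across the three disjoint tissue zones
    (inside tumor / vicinity ring / outside);
``ratio``
    the smoothed log ratio eta between two cell-class counts — within-zone
    pairs form the curated analysis set, and the full grid of cross-zone
    ordered pairs completes the catalogue;
``distance``
    average closest-cell distance between two classes inside tumor regions.

Zones: ``whole`` (entire slide), ``tumor`` (inside segmented tumor regions),
``vicinity`` (the 1 mm ring around them), ``outside`` (everything else).
The three non-whole zones are disjoint and partition the slide.

Exactly 107 entries carry ``structure_flag=True``; they are the default
analysis subset used for response modelling.  The repartition of epithelial
cells inside tumor regions is omitted from the grid because the refinement
step makes it identically zero (epithelial = tumor-class nuclei outside
tumor regions); the corresponding fraction/density grid entries are kept so
that per-zone fractions always sum to one over the full class set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import CLASS_NAMES

__all__ = ["FeatureSpec", "FeatureRegistry", "build_default_registry"]

REGISTRY_VERSION = "1.0"

ZONES = ("whole", "tumor", "vicinity", "outside")
PARTITION_ZONES = ("tumor", "vicinity", "outside")

#: classes 1-6 (granulocyte, lymphocyte, plasma, stromal, tumor, epithelial)
ALL_CLASSES = (1, 2, 3, 4, 5, 6)
#: raw classifier classes 1-5 (no epithelial)
BASE_CLASSES = (1, 2, 3, 4, 5)
#: classes with distance features: granulocyte, lymphocyte, plasma, tumor
DISTANCE_CLASSES = (1, 2, 3, 5)


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: family, zone and the classes it involves."""

    name: str
    family: str  # fraction | density | ratio | repartition | distance
    zone: str  # whole | tumor | vicinity | outside
    source_class: int | None = None
    target_class: int | None = None
    target_zone: str | None = None  # only for cross-zone ratio features
    structure_flag: bool = False


@dataclass
class FeatureRegistry:
    """Ordered, versioned list of feature specs."""

    specs: list[FeatureSpec]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ValueError("feature names are not unique")
        for s in self.specs:
            if s.family == "distance":
                if s.zone != "tumor" or s.source_class not in DISTANCE_CLASSES or (
                    s.target_class not in DISTANCE_CLASSES
                ):
                    raise ValueError(f"invalid distance feature spec: {s}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def structure_subset(self) -> list[FeatureSpec]:
        """The curated tissue-structure analysis subset (107 features)."""
        return [s for s in self.specs if s.structure_flag]

    def structure_names(self) -> list[str]:
        return [s.name for s in self.specs if s.structure_flag]


def build_default_registry() -> FeatureRegistry:
    """Enumerate the default 317-feature catalogue (107 structure-flagged)."""
    specs: list[FeatureSpec] = []
    name = CLASS_NAMES

    # 1. fractions: 4 zones x 6 classes = 24
    for zone in ZONES:
        for cls in ALL_CLASSES:
            specs.append(
                FeatureSpec(
                    name=f"fraction_{name[cls]}_{zone}",
                    family="fraction",
                    zone=zone,
                    source_class=cls,
                    structure_flag=True,
                )
            )

    # 2. densities: 4 zones x 6 classes = 24
    for zone in ZONES:
        for cls in ALL_CLASSES:
            specs.append(
                FeatureSpec(
                    name=f"density_{name[cls]}_{zone}",
                    family="density",
                    zone=zone,
                    source_class=cls,
                    structure_flag=True,
                )
            )

    # 3. repartition: 6 classes x 3 zones, minus epithelial-in-tumor = 17
    for cls in ALL_CLASSES:
        for zone in PARTITION_ZONES:
            if cls == 6 and zone == "tumor":
                continue  # identically zero by construction of the refinement
            specs.append(
                FeatureSpec(
                    name=f"repartition_{name[cls]}_{zone}",
                    family="repartition",
                    zone=zone,
                    source_class=cls,
                    structure_flag=True,
                )
            )

    # 4. within-zone smoothed log ratios: 10 unordered base-class pairs
    #    x zones {whole, tumor, vicinity} = 30
    for zone in ("whole", "tumor", "vicinity"):
        for i, a in enumerate(BASE_CLASSES):
            for b in BASE_CLASSES[i + 1 :]:
                specs.append(
                    FeatureSpec(
                        name=f"ratio_{name[a]}_to_{name[b]}_{zone}",
                        family="ratio",
                        zone=zone,
                        source_class=a,
                        target_class=b,
                        structure_flag=True,
                    )
                )

    # 5. in-tumor closest-cell distances (microns): 12 ordered distinct pairs
    for a in DISTANCE_CLASSES:
        for b in DISTANCE_CLASSES:
            if a == b:
                continue
            specs.append(
                FeatureSpec(
                    name=f"dist_{name[a]}_to_{name[b]}_tumor_um",
                    family="distance",
                    zone="tumor",
                    source_class=a,
                    target_class=b,
                    structure_flag=True,
                )
            )

    # 6. cross-zone ratio grid: ordered distinct pairs of the 15
    #    (base class, partition zone) marks = 15 * 14 = 210
    marks = [(cls, zone) for cls in BASE_CLASSES for zone in PARTITION_ZONES]
    for ca, za in marks:
        for cb, zb in marks:
            if (ca, za) == (cb, zb):
                continue
            specs.append(
                FeatureSpec(
                    name=f"ratio_{name[ca]}_{za}_to_{name[cb]}_{zb}",
                    family="ratio",
                    zone=za,
                    source_class=ca,
                    target_class=cb,
                    target_zone=zb,
                    structure_flag=False,
                )
            )

    registry = FeatureRegistry(specs=specs)
    assert len(registry) == 317, len(registry)
    assert len(registry.structure_subset()) == 107
    return registry
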