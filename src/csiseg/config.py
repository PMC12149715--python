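"""Per-organ configuration: group, contrast window, margins, crop sizes.

The 18 organs at risk of a craniospinal-irradiation plan fall into two
localization groups.  *Body* structures (lungs, kidneys, esophagus, spinal
canal, vertebral bodies, brain, brainstem) are localized coronal-then-
sagittal with organ-specific axial margins: +20 pixels for the lungs, +15
for the spine targets, kidneys and esophagus, +10 for the brain and
brainstem.  *Head* structures (eyes, lenses, optic nerves, chiasm, cochleae)
are localized sagittal-then-axial on bone-window DRRs, with reference boxes
scaled by a factor of two for context.

``max_crop_size`` bounds the ROI per organ; values are calibrated from a
training cohort (per-organ maxima plus margins) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class OrganGroup(str, Enum):
    body = "body"
    head = "head"


class Laterality(str, Enum):
    left = "left"
    right = "right"
    none = "none"


@dataclass
class OrganSpec:
    name: str
    group: OrganGroup
    window: str  # ContrastWindow name used for localization DRRs
    axial_margin: int  # pixels added around the box in the axial plane
    max_crop_size: tuple[int, int, int] | None = None  # (Z, Y, X) voxels
    laterality: Laterality = Laterality.none
    box_scale: float = 1.0  # reference boxes scaled about their center

    def __post_init__(self) -> None:
        self.group = OrganGroup(self.group)
        self.laterality = Laterality(self.laterality)
        if self.axial_margin < 0:
            raise ValueError("axial_margin must be >= 0")
        if self.max_crop_size is not None and any(s <= 0 for s in self.max_crop_size):
            raise ValueError("max_crop_size must be positive")


def _body(name, window, margin, laterality="none"):
    return OrganSpec(name, OrganGroup.body, window, margin, laterality=Laterality(laterality))


def _head(name, laterality="none"):
    # bone window only, x2 reference boxes, no margin at inference
    return OrganSpec(name, OrganGroup.head, "bone", 0,
                     laterality=Laterality(laterality), box_scale=2.0)


#: default localization configuration for the 18 OARs
ORGAN_SPECS: dict[str, OrganSpec] = {s.name: s for s in [
    _body("lung_l", "lung", 20, "left"),
    _body("lung_r", "lung", 20, "right"),
    _body("spinal_canal", "bone", 15),
    _body("vertebral_bodies", "bone", 15),
    _body("kidney_l", "composite", 15, "left"),
    _body("kidney_r", "composite", 15, "right"),
    _body("esophagus", "composite", 15),
    _body("brain", "composite", 10),
    _body("brainstem", "composite", 10),
    _head("eye_l", "left"),
    _head("eye_r", "right"),
    _head("lens_l", "left"),
    _head("lens_r", "right"),
    _head("optic_nerve_l", "left"),
    _head("optic_nerve_r", "right"),
    _head("chiasm"),
    _head("cochlea_l", "left"),
    _head("cochlea_r", "right"),
]}

#: (small, large) containment pairs used to make labels mutually exclusive
CONTAINMENT_PAIRS: list[tuple[str, str]] = [
    ("lens_l", "eye_l"),
    ("lens_r", "eye_r"),
    ("spinal_canal", "vertebral_bodies"),
    ("brainstem", "brain"),
]


def calibrate_max_crop_sizes(
    specs: dict[str, OrganSpec],
    training_rois: dict[str, list[tuple[int, int, int]]],
    slack: int = 4,
) -> None:
    """Set each organ's max_crop_size to the training-cohort maximum + slack."""
    for organ, sizes in training_rois.items():
        if organ not in specs or not sizes:
            continue
        arr = [max(s[i] for s in sizes) + slack for i in range(3)]
        specs[organ].max_crop_size = (arr[0], arr[1], arr[2])
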