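"""Organ localization: orthogonal DRR bounding boxes fused into 3D ROIs.

Stage one of the pipeline.  A 2D detector finds the organ's bounding box on
a DRR in the organ's optimal contrast window; a second detection on an
orthogonal DRR (restricted to the first box's extent) supplies the missing
axis, and the two boxes are fused into a 3D ROI:

* **body structures** — coronal detection (x and z candidates), then a
  sagittal DRR summed only over the coronal box's lateral extent; the ROI
  takes x from the coronal box, y and z from the sagittal box, and is grown
  by an organ-specific margin in the axial plane (+20 px lungs, +15 px
  spine/vertebral bodies/kidneys/esophagus, +10 px brain/brainstem);
* **head structures** — the head region ends at the brainstem's inferior
  border; left/right half sagittal bone-window DRRs are detected first, an
  axial DRR summed over the detected z-range second; reference boxes are
  scaled ×2 for context.

The detector is pluggable: anything honoring :class:`Detector` (fit on
(DRR, box) pairs, predict one box or "not found") can drive the pipeline.
:class:`OracleDetector` reads boxes straight from ground-truth masks and is
used to validate the fusion geometry independently of any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .config import Laterality, OrganGroup, OrganSpec
from .drr import BONE, COMPOSITE, WINDOWS, ContrastWindow, DRRImage, Plane, project
from .io_preproc import BodyMask, CTVolume, LabelSet, derive_body_mask


@dataclass
class Box2D:
    """Half-open, 0-based pixel box on a DRR (u = rows, v = columns)."""

    plane: Plane
    u_range: tuple[int, int]
    v_range: tuple[int, int]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        self.plane = Plane(self.plane)
        for r in (self.u_range, self.v_range):
            if not r[0] < r[1]:
                raise ValueError(f"empty box range {r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    def shifted(self, du: int, dv: int) -> "Box2D":
        return Box2D(self.plane,
                     (self.u_range[0] + du, self.u_range[1] + du),
                     (self.v_range[0] + dv, self.v_range[1] + dv),
                     self.confidence)


@dataclass
class ROI3D:
    """Half-open voxel box: the localization currency."""

    z_range: tuple[int, int]
    y_range: tuple[int, int]
    x_range: tuple[int, int]

    def __post_init__(self) -> None:
        for r in (self.z_range, self.y_range, self.x_range):
            if not r[0] < r[1]:
                raise ValueError(f"empty ROI range {r}")

    @property
    def size(self) -> tuple[int, int, int]:
        return (self.z_range[1] - self.z_range[0],
                self.y_range[1] - self.y_range[0],
                self.x_range[1] - self.x_range[0])

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z_range), slice(*self.y_range), slice(*self.x_range))

    def contains_mask(self, mask: np.ndarray) -> bool:
        idx = np.argwhere(mask)
        if idx.size == 0:
            return False
        lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
        ranges = (self.z_range, self.y_range, self.x_range)
        return all(r[0] <= a and b <= r[1] for r, a, b in zip(ranges, lo, hi))

    def clamped(self, bounds: tuple[int, int, int]) -> "ROI3D":
        rs = []
        for (a, b), n in zip((self.z_range, self.y_range, self.x_range), bounds):
            rs.append((max(0, a), min(n, b)))
        return ROI3D(*rs)


@dataclass
class LocalizationResult:
    organ: str
    patient: str
    roi: ROI3D | None
    status: str  # "ok" | "not_found"
    confidence: float = 0.0


@runtime_checkable
class Detector(Protocol):
    """Contract for any single-class 2D box detector."""

    def fit(self, images: Sequence[DRRImage], boxes: Sequence[Box2D]) -> "Detector": ...

    def predict(self, image: DRRImage) -> Box2D | None:
        """Highest-confidence box in image pixel coordinates, or None."""
        ...


# ---------------------------------------------------------------------------
# reference boxes and the mask-backed oracle detector
# ---------------------------------------------------------------------------

def _mask_projection_axes(plane: Plane) -> tuple[int, int, int]:
    # (projection axis, row axis, column axis) in (z, y, x) order
    if plane == Plane.coronal:
        return 1, 0, 2
    if plane == Plane.sagittal:
        return 2, 0, 1
    return 0, 1, 2


def reference_box_from_mask(
    mask: np.ndarray,
    plane: Plane | str,
    scale: float = 1.0,
    bounds: tuple[int, int] | None = None,
) -> Box2D:
    """Tight box of the mask's planar projection, scaled about its center.

    ``scale`` grows height and width symmetrically (2.0 for head structures,
    to provide context around small organs); the result is clamped to
    ``bounds`` = (n_rows, n_cols) when given.
    """
    plane = Plane(plane)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no reference box")
    _, u_ax, v_ax = _mask_projection_axes(plane)
    idx = np.argwhere(mask)
    ranges = []
    for ax in (u_ax, v_ax):
        lo, hi = int(idx[:, ax].min()), int(idx[:, ax].max()) + 1
        if scale != 1.0:
            c = (lo + hi) / 2.0
            w = hi - lo
            new_w = int(round(scale * w))
            lo = int(np.floor(c - new_w / 2.0))
            hi = lo + new_w
        ranges.append((lo, hi))
    if bounds is not None:
        ranges = [(max(0, a), min(n, b)) for (a, b), n in zip(ranges, bounds)]
    return Box2D(plane, ranges[0], ranges[1], confidence=1.0)


class OracleDetector:
    """Mask-backed detector: predicts the reference box with confidence 1.

    Used to test the fusion geometry independently of any trained model.
    Boxes are returned in the DRR's pixel coordinates (the image origin is
    subtracted), like any trained detector would.
    """

    def __init__(self, labels: LabelSet, organ: str, plane: Plane | str,
                 scale: float = 1.0) -> None:
        self.labels = labels
        self.organ = organ
        self.plane = Plane(plane)
        self.scale = scale

    def fit(self, images, boxes):  # already "trained" by construction
        return self

    def predict(self, image: DRRImage) -> Box2D | None:
        if self.organ not in self.labels:
            return None
        if Plane(image.plane) != self.plane:
            raise ValueError(f"oracle for {self.plane}, got {image.plane} DRR")
        box = reference_box_from_mask(self.labels[self.organ], self.plane, self.scale)
        box = box.shifted(-image.origin[0], -image.origin[1])
        H, W = image.shape
        u = (max(0, box.u_range[0]), min(H, box.u_range[1]))
        v = (max(0, box.v_range[0]), min(W, box.v_range[1]))
        if u[0] >= u[1] or v[0] >= v[1]:
            return None  # organ projects outside this (cropped) DRR
        return Box2D(self.plane, u, v, confidence=1.0)


def oracle_detector(labels: LabelSet, organ: str, plane: Plane | str,
                    scale: float = 1.0) -> OracleDetector:
    return OracleDetector(labels, organ, plane, scale)


# ---------------------------------------------------------------------------
# DRR construction helpers used at inference
# ---------------------------------------------------------------------------

def restricted_sagittal_drr(
    vol: CTVolume, x_range: tuple[int, int], w: ContrastWindow
) -> DRRImage:
    """Sagittal DRR summed only over the lateral extent of a coronal box."""
    return project(vol, Plane.sagittal, x_range, w)


def head_region(vol: CTVolume, labels: LabelSet | None = None,
                brainstem_roi: ROI3D | None = None) -> tuple[int, int]:
    """Head z-range: volume top down to the brainstem's inferior border."""
    if labels is not None and "brainstem" in labels:
        z_inf = int(np.argwhere(labels["brainstem"])[:, 0].max()) + 1
    elif brainstem_roi is not None:
        z_inf = brainstem_roi.z_range[1]
    else:
        raise ValueError("brainstem mask or localization required to find the head")
    return (0, z_inf)


def _head_sagittal(vol: CTVolume, head_z: tuple[int, int],
                   x_range: tuple[int, int], w: ContrastWindow) -> DRRImage:
    z0, z1 = head_z
    if not (0 <= z0 < z1 <= vol.shape[0]):
        raise ValueError(f"bad head z-range {head_z}")
    sub = CTVolume(vol.voxels[z0:z1], vol.spacing, vol.id)
    d = project(sub, Plane.sagittal, x_range, w)
    d.origin = (z0, 0)
    return d


def split_sagittal_drrs(
    vol: CTVolume,
    head_z: tuple[int, int],
    w: ContrastWindow = BONE,
    body: BodyMask | None = None,
) -> tuple[DRRImage, DRRImage]:
    """Left and right half sagittal DRRs of the head (bone window only).

    The midline is the body's lateral centroid column within the head
    region; the left image sums x in [0, mid), the right x in [mid, X).
    """
    if w.name != BONE.name:
        raise ValueError("head structures use the bone window only")
    if body is None:
        body = getattr(vol, "body", None) or derive_body_mask(vol)
    z0, z1 = head_z
    cols = np.argwhere(body.mask[z0:z1])
    if cols.size == 0:
        raise ValueError("no body voxels in the head region")
    mid = int(np.floor(cols[:, 2].mean()))
    X = vol.shape[2]
    if not (0 < mid < X):
        raise ValueError("degenerate midline split")
    left = _head_sagittal(vol, head_z, (0, mid), w)
    right = _head_sagittal(vol, head_z, (mid, X), w)
    return left, right


# ---------------------------------------------------------------------------
# box fusion and ROI post-processing
# ---------------------------------------------------------------------------

def fuse_body_boxes(coronal: Box2D, sagittal: Box2D) -> ROI3D:
    """Integrate coronal (x) with sagittal (z, y) box coordinates."""
    if Plane(coronal.plane) != Plane.coronal:
        raise ValueError(f"first box must be coronal, got {coronal.plane}")
    if Plane(sagittal.plane) != Plane.sagittal:
        raise ValueError(f"second box must be sagittal, got {sagittal.plane}")
    return ROI3D(z_range=sagittal.u_range, y_range=sagittal.v_range,
                 x_range=coronal.v_range)


def fuse_head_boxes(sagittal: Box2D, axial: Box2D) -> ROI3D:
    """z from the sagittal box; y and x from the axial box."""
    if Plane(sagittal.plane) != Plane.sagittal:
        raise ValueError(f"first box must be sagittal, got {sagittal.plane}")
    if Plane(axial.plane) != Plane.axial:
        raise ValueError(f"second box must be axial, got {axial.plane}")
    return ROI3D(z_range=sagittal.u_range, y_range=axial.u_range,
                 x_range=axial.v_range)


def expand_axial(roi: ROI3D, margin: int, bounds: tuple[int, int, int]) -> ROI3D:
    """Grow the ROI by ``margin`` pixels per side in the axial (y, x) plane.

    The superior-inferior extent is untouched; the result is clamped to the
    volume bounds.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    return ROI3D(
        z_range=(max(0, roi.z_range[0]), min(bounds[0], roi.z_range[1])),
        y_range=(max(0, roi.y_range[0] - margin), min(bounds[1], roi.y_range[1] + margin)),
        x_range=(max(0, roi.x_range[0] - margin), min(bounds[2], roi.x_range[1] + margin)),
    )


def clip_to_max_size(roi: ROI3D, max_size: tuple[int, int, int] | None) -> ROI3D:
    """Shrink the ROI symmetrically about its center where it exceeds the cap."""
    if max_size is None:
        return roi
    ranges = []
    for (a, b), cap in zip((roi.z_range, roi.y_range, roi.x_range), max_size):
        w = b - a
        if w > cap:
            excess = w - cap
            a += excess // 2
            b = a + cap
        ranges.append((a, b))
    return ROI3D(*ranges)


# ---------------------------------------------------------------------------
# full per-organ procedures
# ---------------------------------------------------------------------------

def _window(spec: OrganSpec) -> ContrastWindow:
    return WINDOWS[spec.window]


def localize_body_organ(
    vol: CTVolume,
    spec: OrganSpec,
    det_coronal: Detector,
    det_sagittal: Detector,
) -> LocalizationResult:
    """Coronal detection → restricted sagittal DRR → sagittal detection →
    fusion → axial margin → max-size clip."""
    if spec.group != OrganGroup.body:
        raise ValueError(f"{spec.name} is not a body structure")
    w = _window(spec)
    cor = det_coronal.predict(project(vol, Plane.coronal, None, w))
    if cor is None:
        return LocalizationResult(spec.name, vol.id, None, "not_found")
    sag_img = restricted_sagittal_drr(vol, cor.v_range, w)
    sag = det_sagittal.predict(sag_img)
    if sag is None:
        return LocalizationResult(spec.name, vol.id, None, "not_found")
    roi = fuse_body_boxes(cor, sag)
    roi = expand_axial(roi, spec.axial_margin, vol.shape)
    roi = clip_to_max_size(roi, spec.max_crop_size).clamped(vol.shape)
    return LocalizationResult(spec.name, vol.id, roi, "ok",
                              min(cor.confidence, sag.confidence))


def localize_head_organ(
    vol: CTVolume,
    spec: OrganSpec,
    det_sagittal: Detector,
    det_axial: Detector,
    head_z: tuple[int, int],
    body: BodyMask | None = None,
) -> LocalizationResult:
    """Half-sagittal detection → axial DRR over the detected z-range →
    axial detection → fusion → max-size clip.

    The laterality of the organ selects the left or right half sagittal
    DRR; midline organs use the full lateral extent of the head.
    """
    if spec.group != OrganGroup.head:
        raise ValueError(f"{spec.name} is not a head structure")
    if spec.laterality == Laterality.none:
        sag_img = _head_sagittal(vol, head_z, None, BONE)
    else:
        left, right = split_sagittal_drrs(vol, head_z, BONE, body)
        sag_img = left if spec.laterality == Laterality.left else right
    sag = det_sagittal.predict(sag_img)
    if sag is None:
        return LocalizationResult(spec.name, vol.id, None, "not_found")
    sag = sag.shifted(sag_img.origin[0], sag_img.origin[1])  # back to volume z
    z0 = max(0, sag.u_range[0])
    z1 = min(vol.shape[0], sag.u_range[1])
    if z0 >= z1:
        return LocalizationResult(spec.name, vol.id, None, "not_found")
    ax = det_axial.predict(project(vol, Plane.axial, (z0, z1), BONE))
    if ax is None:
        return LocalizationResult(spec.name, vol.id, None, "not_found")
    roi = fuse_head_boxes(Box2D(Plane.sagittal, (z0, z1), sag.v_range,
                                sag.confidence), ax)
    roi = expand_axial(roi, spec.axial_margin, vol.shape)
    roi = clip_to_max_size(roi, spec.max_crop_size).clamped(vol.shape)
    return LocalizationResult(spec.name, vol.id, roi, "ok",
                              min(sag.confidence, ax.confidence))


def localize_organ(
    vol: CTVolume,
    spec: OrganSpec,
    detectors: dict[Plane, Detector],
    head_z: tuple[int, int] | None = None,
    body: BodyMask | None = None,
) -> LocalizationResult:
    if spec.group == OrganGroup.body:
        return localize_body_organ(vol, spec, detectors[Plane.coronal],
                                   detectors[Plane.sagittal])
    if head_z is None:
        raise ValueError("head organs need the head z-range")
    return localize_head_organ(vol, spec, detectors[Plane.sagittal],
                               detectors[Plane.axial], head_z, body)
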