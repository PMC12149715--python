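"""Digitally reconstructed radiographs (DRRs) by axis-parallel summation.

A DRR here is a parallel projection: the HU grid is clamped to a contrast
window, summed along one canonical axis over a half-open slice interval, and
min-max normalized to 0–255 integers.  Three scalar windows (lung, soft
tissue, bone) and their 3-channel composite reproduce radiograph-like views
in which specific tissue classes dominate.

Plane conventions (under the (z, y, x) volume order):

* ``coronal``  — sum over y; image rows = z, columns = x
* ``sagittal`` — sum over x; image rows = z, columns = y
* ``axial``    — sum over z; image rows = y, columns = x
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .io_preproc import CTVolume


class Plane(str, Enum):
    coronal = "coronal"
    sagittal = "sagittal"
    axial = "axial"


#: projection axis in (z, y, x) order for each plane
PROJECTION_AXIS = {Plane.coronal: 1, Plane.sagittal: 2, Plane.axial: 0}


@dataclass(frozen=True)
class ContrastWindow:
    name: str
    lo: float | None
    hi: float | None

    def __post_init__(self) -> None:
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ValueError(f"window {self.name}: lo must be < hi")

    @property
    def is_composite(self) -> bool:
        return self.lo is None or self.hi is None


LUNG = ContrastWindow("lung", -1500.0, 0.0)
SOFT_TISSUE = ContrastWindow("soft_tissue", 0.0, 50.0)
BONE = ContrastWindow("bone", 250.0, 3000.0)
COMPOSITE = ContrastWindow("composite", None, None)

WINDOWS = {w.name: w for w in (LUNG, SOFT_TISSUE, BONE, COMPOSITE)}


@dataclass
class DRRImage:
    """A 0–255 projection image with its provenance.

    ``origin`` is the (row, column) volume index of pixel (0, 0); it is
    nonzero when the image was cropped (e.g. head-region sagittal DRRs), so
    detected boxes can be mapped back to absolute volume coordinates.
    """

    pixels: np.ndarray  # (H, W) or (H, W, 3), integers in [0, 255]
    plane: Plane
    summed_range: tuple[int, int]
    window: ContrastWindow
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.plane = Plane(self.plane)
        p = np.asarray(self.pixels)
        if p.ndim not in (2, 3) or (p.ndim == 3 and p.shape[2] != 3):
            raise ValueError(f"bad DRR pixel shape {p.shape}")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("DRR pixels must lie in [0, 255]")
        self.pixels = p

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def clip_to_window(vol: CTVolume, w: ContrastWindow) -> CTVolume:
    """Clamp HU values into a scalar contrast window."""
    if w.is_composite:
        raise ValueError("composite window: build channels from the scalar windows")
    return CTVolume(np.clip(vol.voxels, w.lo, w.hi), vol.spacing, vol.id)


def _normalize_255(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int16)
    scaled = (img - lo) * (255.0 / (hi - lo))
    # half-to-even rounding for bit-stable output across platforms
    return np.rint(scaled).astype(np.int16)


def project(
    vol: CTVolume,
    plane: Plane | str,
    summed_range: tuple[int, int] | None = None,
    w: ContrastWindow = COMPOSITE,
) -> DRRImage:
    """Sum the windowed volume along one axis and normalize to 0–255.

    ``summed_range`` is a half-open index interval along the projection axis
    (defaults to the full extent).  A composite window yields a 3-channel
    image with (lung, soft tissue, bone) channels.
    """
    plane = Plane(plane)
    axis = PROJECTION_AXIS[plane]
    n = vol.shape[axis]
    if summed_range is None:
        summed_range = (0, n)
    a, b = summed_range
    if not (0 <= a < b <= n):
        raise ValueError(f"empty or out-of-bounds summed_range {summed_range}")

    if w.is_composite:
        parts = [project(vol, plane, summed_range, sw) for sw in (LUNG, SOFT_TISSUE, BONE)]
        return compose_channels(*parts)

    sl = [slice(None)] * 3
    sl[axis] = slice(a, b)
    clipped = np.clip(vol.voxels[tuple(sl)], w.lo, w.hi)
    img = clipped.sum(axis=axis, dtype=np.float64)
    return DRRImage(_normalize_255(img), plane, (int(a), int(b)), w)


def compose_channels(lung: DRRImage, soft: DRRImage, bone: DRRImage) -> DRRImage:
    """Stack lung/soft-tissue/bone DRRs into one 3-channel composite image."""
    imgs = (lung, soft, bone)
    for d, expected in zip(imgs, (LUNG.name, SOFT_TISSUE.name, BONE.name)):
        if d.window.name != expected:
            raise ValueError(f"expected a {expected} DRR, got {d.window.name}")
        if d.n_channels != 1:
            raise ValueError("compose_channels takes single-channel DRRs")
    if len({d.shape for d in imgs}) != 1:
        raise ValueError("channel shapes differ")
    if len({d.plane for d in imgs}) != 1:
        raise ValueError("channel planes differ")
    if len({d.summed_range for d in imgs}) != 1:
        raise ValueError("channel summed ranges differ")
    if len({d.origin for d in imgs}) != 1:
        raise ValueError("channel origins differ")
    pixels = np.stack([d.pixels for d in imgs], axis=2)
    return DRRImage(pixels, lung.plane, lung.summed_range, COMPOSITE, lung.origin)


def replicate_channels(d: DRRImage) -> DRRImage:
    """Duplicate a single-channel DRR into 3 identical channels."""
    if d.n_channels != 1:
        raise ValueError("input already has 3 channels")
    return replace(d, pixels=np.repeat(d.pixels[:, :, None], 3, axis=2))


def as_3channel(d: DRRImage) -> DRRImage:
    return d if d.n_channels == 3 else replicate_channels(d)


def crop_rows(d: DRRImage, u_range: tuple[int, int]) -> DRRImage:
    """Crop image rows, tracking the origin so boxes map back to the volume."""
    a, b = u_range
    if not (0 <= a < b <= d.shape[0]):
        raise ValueError(f"bad row range {u_range}")
    return replace(
        d, pixels=d.pixels[a:b], origin=(d.origin[0] + a, d.origin[1])
    )


def save_png(d: DRRImage, path) -> None:
    from PIL import Image

    Image.fromarray(d.pixels.astype(np.uint8)).save(str(path))
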