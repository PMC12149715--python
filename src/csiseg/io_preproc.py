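"""NIfTI I/O and shared whole-body CT preprocessing.

All volumes live in a single canonical axis order ``(z, y, x)``:

* ``z`` — superior → inferior (index 0 is the top of the head),
* ``y`` — anterior → posterior,
* ``x`` — patient-left → patient-right.

Conversion from arbitrary (orthogonal) on-disk orientations happens once, in
:func:`load_volume`; every other module assumes this convention.  The shared
preprocessing mirrors a treatment-planning workflow: voxels outside the body
contour are forced to air (−1000 HU), the patient is centered on a fixed
axial canvas, overlapping labels are made mutually exclusive, and volumes can
be resampled to a common grid with nearest-neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

AIR_HU = -1000.0
#: default HU threshold separating body tissue from air when no contour exists
BODY_THRESHOLD_HU = -300.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class Cohort(str, Enum):
    train = "train"
    validation = "validation"
    test = "test"


@dataclass
class CTVolume:
    """A 3D HU-valued CT grid in canonical (z, y, x) order."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm / voxel
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D array, got {self.voxels.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelSet:
    """Named binary organ masks aligned to one CTVolume."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, m in self.masks.items():
            m = np.asarray(m)
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"mask {name!r} is not binary")
            m = m.astype(bool)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} differs from {shape}"
                )
            clean[name] = m
        self.masks = clean

    def __getitem__(self, organ: str) -> np.ndarray:
        return self.masks[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.masks

    @property
    def organs(self) -> list[str]:
        return list(self.masks)


class BodyMaskSource(str, Enum):
    provided = "provided"
    derived = "derived"


@dataclass
class BodyMask:
    mask: np.ndarray
    source: BodyMaskSource = BodyMaskSource.derived

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError("body mask is empty")


@dataclass
class PatientMeta:
    id: str
    age: float
    cohort: Cohort = Cohort.train

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        self.cohort = Cohort(self.cohort)


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def _canonical_from_ras(data: np.ndarray, zooms: tuple) -> tuple[np.ndarray, tuple]:
    # RAS+: i -> Right, j -> Anterior, k -> Superior.  Canonical z runs
    # superior->inferior and y anterior->posterior, so both are flipped; x
    # (left->right) coincides with +R.
    vol = np.ascontiguousarray(np.transpose(data, (2, 1, 0))[::-1, ::-1, :])
    dz, dy, dx = zooms[2], zooms[1], zooms[0]
    return vol, (float(dz), float(dy), float(dx))


def load_volume(path: str | Path, id: str | None = None) -> CTVolume:
    """Load a NIfTI image into canonical (z, y, x) order.

    The on-disk orientation is read from the affine; any orthogonal
    orientation is accepted and reoriented.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    vol, spacing = _canonical_from_ras(data, img.header.get_zooms())
    return CTVolume(vol, spacing, id=id if id is not None else path.name.split(".")[0])


def save_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a canonical volume as RAS+ NIfTI (inverse of :func:`load_volume`)."""
    data = np.ascontiguousarray(np.transpose(vol.voxels[::-1, ::-1, :], (2, 1, 0)))
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_mask(mask: np.ndarray, spacing: tuple, path: str | Path) -> None:
    save_volume(CTVolume(np.asarray(mask, dtype=np.uint8), spacing), path)


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple]:
    vol = load_volume(path)
    return vol.voxels > 0.5, vol.spacing


def mask_path(directory: str | Path, patient: str, organ: str) -> Path:
    return Path(directory) / f"{patient}_{organ}.nii.gz"


def save_labels(labels: LabelSet, spacing: tuple, directory: str | Path,
                patient: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for organ, m in labels.masks.items():
        save_mask(m, spacing, mask_path(directory, patient, organ))


def load_labels(directory: str | Path, patient: str) -> LabelSet:
    directory = Path(directory)
    masks = {}
    for p in sorted(directory.glob(f"{patient}_*.nii.gz")):
        organ = p.name[len(patient) + 1:].split(".")[0]
        masks[organ], _ = load_mask(p)
    return LabelSet(masks)


# ---------------------------------------------------------------------------
# Body masking
# ---------------------------------------------------------------------------

def derive_body_mask(vol: CTVolume, threshold: float = BODY_THRESHOLD_HU) -> BodyMask:
    """Threshold the HU grid and keep the largest 26-connected component.

    A stand-in for the clinical body contour: tissue is everything above
    ``threshold`` (default −300 HU); internal air cavities are closed by
    slice-wise hole filling.
    """
    fg = vol.voxels > threshold
    if not fg.any():
        raise ValueError("no body found above threshold")
    lab, n = ndimage.label(fg, structure=_STRUCT_26)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        fg = lab == np.argmax(sizes)
    filled = np.empty_like(fg)
    for z in range(fg.shape[0]):
        filled[z] = ndimage.binary_fill_holes(fg[z])
    return BodyMask(filled, BodyMaskSource.derived)


def mask_outside_body(vol: CTVolume, body: BodyMask) -> CTVolume:
    """Set every voxel outside the body contour to −1000 HU."""
    if body.mask.shape != vol.shape:
        raise ValueError(
            f"body mask shape {body.mask.shape} != volume shape {vol.shape}"
        )
    out = np.where(body.mask, vol.voxels, AIR_HU)
    return CTVolume(out, vol.spacing, vol.id)


# ---------------------------------------------------------------------------
# Canvas centering
# ---------------------------------------------------------------------------

def centering_offset(body: BodyMask, canvas: tuple[int, int]) -> tuple[int, int]:
    """(dy, dx) translation that maps the body centroid to the canvas center.

    The centroid is rounded toward −infinity, as is the canvas center.
    """
    W_x, H_y = canvas
    coords = np.argwhere(body.mask)
    cy = int(np.floor(coords[:, 1].mean()))
    cx = int(np.floor(coords[:, 2].mean()))
    return H_y // 2 - cy, W_x // 2 - cx


def center_on_canvas(
    vol: CTVolume,
    labels: LabelSet | None = None,
    canvas: tuple[int, int] = (512, 256),
    body: BodyMask | None = None,
) -> tuple[CTVolume, LabelSet | None]:
    """Place the patient at the center of a fixed axial canvas.

    ``canvas`` is (W_x, H_y); the default reproduces axial slices 512 pixels
    wide (lateral) by 256 tall (anterior-posterior).  The volume is padded
    with −1000 HU and masks with 0.  Raises if the body does not fit —
    resample to a coarser grid first.
    """
    if body is None:
        body = derive_body_mask(vol)
    W_x, H_y = canvas
    Z = vol.shape[0]
    dy, dx = centering_offset(body, canvas)

    coords = np.argwhere(body.mask)
    y0, y1 = coords[:, 1].min() + dy, coords[:, 1].max() + dy
    x0, x1 = coords[:, 2].min() + dx, coords[:, 2].max() + dx
    if y0 < 0 or x0 < 0 or y1 >= H_y or x1 >= W_x:
        raise ValueError(
            "body does not fit the canvas after centering; resample to a "
            "coarser spacing first"
        )

    def shift(arr: np.ndarray, pad_value) -> np.ndarray:
        out = np.full((Z, H_y, W_x), pad_value, dtype=arr.dtype)
        ys0, ys1 = max(0, -dy), min(arr.shape[1], H_y - dy)
        xs0, xs1 = max(0, -dx), min(arr.shape[2], W_x - dx)
        out[:, ys0 + dy:ys1 + dy, xs0 + dx:xs1 + dx] = arr[:, ys0:ys1, xs0:xs1]
        return out

    new_vol = CTVolume(shift(vol.voxels, AIR_HU), vol.spacing, vol.id)
    new_labels = None
    if labels is not None:
        new_labels = LabelSet({k: shift(m, False) for k, m in labels.masks.items()})
    return new_vol, new_labels


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _nearest_indices(n_in: int, n_out: int) -> np.ndarray:
    # center-aligned nearest-neighbor index map
    idx = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(int)
    return np.clip(idx, 0, n_in - 1)


def resample_nearest(
    vol: CTVolume,
    labels: LabelSet | None,
    target_spacing: tuple[float, float, float],
) -> tuple[CTVolume, LabelSet | None]:
    """Resample volume and masks to ``target_spacing`` with nearest neighbor.

    Nearest neighbor is used for intensities as well as masks, so binarity is
    preserved exactly and no new HU values are invented.  Output shape is
    ``round(shape * spacing / target_spacing)`` per axis.
    """
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive floats: {target_spacing}")
    shape_out = tuple(
        int(np.round(n * s / t))
        for n, s, t in zip(vol.shape, vol.spacing, target_spacing)
    )
    if any(n == 0 for n in shape_out):
        raise ValueError(f"degenerate output shape {shape_out}")
    if shape_out == vol.shape and tuple(target_spacing) == tuple(vol.spacing):
        return vol, labels
    ix = [_nearest_indices(n_in, n_out) for n_in, n_out in zip(vol.shape, shape_out)]

    def take(arr: np.ndarray) -> np.ndarray:
        return arr[np.ix_(ix[0], ix[1], ix[2])]

    new_vol = CTVolume(take(vol.voxels), tuple(float(t) for t in target_spacing), vol.id)
    new_labels = None
    if labels is not None:
        new_labels = LabelSet({k: take(m) for k, m in labels.masks.items()})
    return new_vol, new_labels


# ---------------------------------------------------------------------------
# Label exclusivity
# ---------------------------------------------------------------------------

def make_labels_exclusive(
    labels: LabelSet, containment: list[tuple[str, str]]
) -> LabelSet:
    """Crop smaller structures out of the larger ones they overlap with.

    ``containment`` lists (small, large) organ pairs; for each, the large
    mask loses the small mask's voxels while the small mask is untouched.
    Idempotent.
    """
    masks = {k: m.copy() for k, m in labels.masks.items()}
    for small, large in containment:
        if small not in masks:
            raise KeyError(f"unknown organ {small!r} in containment pair")
        if large not in masks:
            raise KeyError(f"unknown organ {large!r} in containment pair")
        masks[large] &= ~masks[small]
    return LabelSet(masks)
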