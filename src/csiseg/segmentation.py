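"""Organ-specific segmentation: mini-CT extraction, U-Net training, post-processing.

Stage two of the pipeline.  The localized ROI is cropped out of the
whole-body scan into a *mini-CT*, intensity-clipped, normalized to [0, 1]
and zero-padded to the organ's uniform input size.  Body organs use a
percentile clip range — the 10th/90th HU percentiles taken inside the
reference mask and inside a 2 mm rim around it (lowest low, highest high);
head structures use a fixed 0–250 HU window.  Since no reference mask
exists at inference, per-case training ranges are aggregated to an
organ-level range by the median rule and frozen in the organ's config.

Training slices the mini-CTs axially.  The basic and attention U-Nets see
single slices; the 2.5D variant sees the target slice sandwiched between
its superior and inferior neighbors as 3 channels (edge slices replicate
the missing neighbor).  Augmentation applies, with probability 0.5, an
in-axial-plane rotation within ±15° and isotropic scaling within ±15%,
identically to image and mask.  Predictions pass through a sigmoid, are
thresholded at 0.5, reduced to the largest 26-connected component, and
pasted back into the whole-body frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_preproc import CTVolume
from .localization import ROI3D
from .nets import Adam, UNet, dice_bce_with_logits

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: fixed clip window for the small head structures, in HU
HEAD_CLIP = (0.0, 250.0)


class ModelVariant(str, Enum):
    basic_unet = "basic_unet"
    attention_unet = "attention_unet"
    unet_2p5d = "unet_2p5d"


@dataclass(frozen=True)
class ClipRange:
    lo: float
    hi: float
    organ: str = ""
    source: str = "percentile_rule"  # percentile_rule | head_fixed | config

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"clip range must have lo < hi, got [{self.lo}, {self.hi}]")


@dataclass
class MiniCT:
    """A cropped, clipped, normalized, padded organ-specific sub-volume."""

    voxels: np.ndarray  # (Z, Y, X), values in [0, 1], padded with 0
    roi: ROI3D          # placement of the (unpadded) crop in the parent
    organ: str
    pad_before: tuple[int, int, int]
    pad_value: float = 0.0

    @property
    def crop_shape(self) -> tuple[int, int, int]:
        return self.roi.size


@dataclass
class TrainConfig:
    seed: int = 0
    epochs: int = 40
    batch_size: int = 8
    lr: float = 3e-3
    rotation_deg: float = 15.0
    scale_limit: float = 0.15
    augment_prob: float = 0.5
    threshold: float = 0.5
    widths: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self) -> None:
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must lie in [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# intensity clipping
# ---------------------------------------------------------------------------

def _rim(mask: np.ndarray, spacing, rim_mm: float) -> np.ndarray:
    # ellipsoidal structuring element: rim_mm converted to voxels per axis,
    # rounded up
    radii = [int(np.ceil(rim_mm / s)) for s in spacing]
    zz, yy, xx = np.ogrid[-radii[0]:radii[0] + 1,
                          -radii[1]:radii[1] + 1,
                          -radii[2]:radii[2] + 1]
    selem = ((zz / radii[0]) ** 2 + (yy / radii[1]) ** 2
             + (xx / radii[2]) ** 2) <= 1.0
    return ndimage.binary_dilation(mask, structure=selem) & ~mask


def compute_clip_range(
    vol: CTVolume, mask: np.ndarray, organ: str = "", rim_mm: float = 2.0
) -> ClipRange:
    """Percentile clip range from the reference mask and its 2 mm rim.

    lo = min(P10 inside, P10 rim); hi = max(P90 inside, P90 rim).  If the
    rim is empty the inside percentiles alone are used; a degenerate
    (constant) result is widened by ±1 HU.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    inside = vol.voxels[mask]
    rim = _rim(mask, vol.spacing, rim_mm)
    rim_vals = vol.voxels[rim]
    lo = float(np.percentile(inside, 10))
    hi = float(np.percentile(inside, 90))
    if rim_vals.size:
        lo = min(lo, float(np.percentile(rim_vals, 10)))
        hi = max(hi, float(np.percentile(rim_vals, 90)))
    if lo >= hi:  # constant-intensity degenerate case
        lo, hi = lo - 1.0, hi + 1.0
    return ClipRange(lo, hi, organ, "percentile_rule")


def head_clip_range(organ: str = "") -> ClipRange:
    return ClipRange(*HEAD_CLIP, organ, "head_fixed")


def aggregate_clip_range(per_case: list[ClipRange]) -> ClipRange:
    """Organ-level clip range for inference: medians of the case bounds."""
    if not per_case:
        raise ValueError("no case ranges to aggregate")
    lo = float(np.median([c.lo for c in per_case]))
    hi = float(np.median([c.hi for c in per_case]))
    organ = per_case[0].organ
    if lo >= hi:
        lo, hi = lo - 1.0, hi + 1.0
    return ClipRange(lo, hi, organ, "config")


# ---------------------------------------------------------------------------
# mini-CT extraction and paste-back
# ---------------------------------------------------------------------------

def extract_mini_ct(
    vol: CTVolume,
    roi: ROI3D,
    organ: str,
    uniform_size: tuple[int, int, int],
    clip: ClipRange,
) -> MiniCT:
    """Crop → clamp to the clip range → map [lo, hi] → [0, 1] → pad.

    Normalization precedes padding, so the pad value 0 coincides with the
    clip minimum and the network sees a constant background.
    """
    shape = vol.shape
    for (a, b), n in zip((roi.z_range, roi.y_range, roi.x_range), shape):
        if a < 0 or b > n:
            raise ValueError(f"ROI {roi} exceeds the volume shape {shape}")
    crop = vol.voxels[roi.slices()].astype(np.float32)
    if any(c > u for c, u in zip(crop.shape, uniform_size)):
        raise ValueError(
            f"ROI size {crop.shape} exceeds uniform size {uniform_size}; "
            "localization should have clipped it"
        )
    crop = np.clip(crop, clip.lo, clip.hi)
    crop = (crop - clip.lo) / (clip.hi - clip.lo)
    pad_before = tuple((u - c) // 2 for c, u in zip(crop.shape, uniform_size))
    pad = [(pb, u - c - pb) for pb, c, u in zip(pad_before, crop.shape, uniform_size)]
    return MiniCT(np.pad(crop, pad), roi, organ, pad_before)


def crop_mask_to_mini(mask: np.ndarray, mini: MiniCT) -> np.ndarray:
    """Reference mask in the mini-CT frame (same crop + padding)."""
    crop = np.asarray(mask).astype(bool)[mini.roi.slices()]
    pad = [(pb, u - c - pb) for pb, c, u in
           zip(mini.pad_before, crop.shape, mini.voxels.shape)]
    return np.pad(crop, pad)


def paste_back(
    mini_mask: np.ndarray, mini: MiniCT, parent_shape: tuple[int, int, int]
) -> np.ndarray:
    """Strip the padding and place the mask at the ROI in a zero background."""
    roi = mini.roi
    for (a, b), n in zip((roi.z_range, roi.y_range, roi.x_range), parent_shape):
        if a < 0 or b > n:
            raise ValueError(f"ROI {roi} lies outside the parent shape {parent_shape}")
    pz, py, px = mini.pad_before
    dz, dy, dx = roi.size
    core = np.asarray(mini_mask).astype(bool)[pz:pz + dz, py:py + dy, px:px + dx]
    out = np.zeros(parent_shape, dtype=bool)
    out[roi.slices()] = core
    return out


# ---------------------------------------------------------------------------
# augmentation and 2.5D stacks
# ---------------------------------------------------------------------------

def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random in-axial-plane rotation (±15°) and scaling (±15%), p = 0.5.

    The same transform hits image (linear interpolation) and mask (nearest);
    with probability 1 − augment_prob both are returned unchanged.  The rng
    is always consumed identically so the draw sequence is reproducible.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    u = rng.uniform()
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    scale = rng.uniform(1.0 - cfg.scale_limit, 1.0 + cfg.scale_limit)
    if u >= cfg.augment_prob:
        return image, mask
    th = np.deg2rad(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # output->input map: inverse rotation divided by the zoom factor
    mat2 = rot.T / scale
    matrix = np.zeros((3, 3))
    matrix[0, 0] = 1.0
    matrix[1:, 1:] = mat2
    center = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    offset = center - matrix @ center
    img_t = ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                     mode="constant", cval=0.0)
    msk_t = ndimage.affine_transform(mask.astype(np.float32), matrix,
                                     offset=offset, order=0, cval=0.0)
    return img_t.astype(np.float32), msk_t > 0.5


def make_2p5d_stacks(voxels: np.ndarray) -> np.ndarray:
    """(Z, Y, X) → (Z, 3, Y, X): each slice between its axial neighbors.

    Channel order is (superior, target, inferior); at the first/last slice
    the missing neighbor is the edge slice itself.
    """
    v = np.asarray(voxels)
    sup = np.concatenate([v[:1], v[:-1]], axis=0)
    inf = np.concatenate([v[1:], v[-1:]], axis=0)
    return np.stack([sup, v, inf], axis=1)


# ---------------------------------------------------------------------------
# model construction / training / inference
# ---------------------------------------------------------------------------

def build_model(variant: ModelVariant | str, cfg: TrainConfig | None = None) -> UNet:
    """Instantiate a segmentation network for the given variant."""
    variant = ModelVariant(variant)
    cfg = cfg or TrainConfig()
    if variant == ModelVariant.basic_unet:
        return UNet(1, cfg.widths, attention=False, seed=cfg.seed)
    if variant == ModelVariant.attention_unet:
        return UNet(1, cfg.widths, attention=True, seed=cfg.seed)
    if variant == ModelVariant.unet_2p5d:
        return UNet(3, cfg.widths, attention=False, seed=cfg.seed)
    raise ValueError(f"unknown variant {variant}")


def _slice_inputs(voxels: np.ndarray, variant: ModelVariant) -> np.ndarray:
    if variant == ModelVariant.unet_2p5d:
        return make_2p5d_stacks(voxels).astype(np.float32)
    return voxels[:, None].astype(np.float32)  # (Z, 1, Y, X)


@dataclass
class SegmenterResult:
    model: UNet
    variant: ModelVariant
    loss_trace: list[float]
    config: TrainConfig


def train_segmenter(
    variant: ModelVariant | str,
    dataset: list[tuple[MiniCT, np.ndarray]],
    cfg: TrainConfig,
) -> SegmenterResult:
    """Train one organ-specific network on (mini-CT, mask) pairs.

    Masks are in the mini-CT frame.  Training runs on axial slices with
    soft-Dice + BCE loss and Adam; augmentation resamples each mini-CT
    every epoch.  Fully deterministic for a fixed ``cfg.seed``.
    """
    variant = ModelVariant(variant)
    if not dataset:
        raise ValueError("empty training dataset")
    f = 2 ** (len(cfg.widths) - 1)
    for mini, mask in dataset:
        if mini.voxels.shape != mask.shape:
            raise ValueError("mini-CT and mask shapes differ")
        if mini.voxels.shape[1] % f or mini.voxels.shape[2] % f:
            raise ValueError(
                f"axial dims of {mini.voxels.shape} must be divisible by {f}"
            )
    model = build_model(variant, cfg)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 17)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        xs, ts = [], []
        for mini, mask in dataset:
            img, msk = augment_pair(mini.voxels, mask, cfg, rng)
            xs.append(_slice_inputs(img, variant))
            ts.append(msk[:, None].astype(np.float32))
        X = np.concatenate(xs)
        T = np.concatenate(ts)
        order = rng.permutation(len(X))
        ep_loss = 0.0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(X[idx])
            loss, grad = dice_bce_with_logits(logits, T[idx])
            logits.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        trace.append(ep_loss / len(X))
    return SegmenterResult(model, variant, trace, cfg)


def predict_mask(
    model: UNet,
    mini: MiniCT,
    threshold: float = 0.5,
    variant: ModelVariant | str = ModelVariant.basic_unet,
    batch_size: int = 16,
) -> np.ndarray:
    """Slice-wise sigmoid probabilities thresholded into a 3D binary mask."""
    variant = ModelVariant(variant)
    X = _slice_inputs(mini.voxels, variant)
    if X.shape[1] != model.in_channels:
        raise ValueError(
            f"model expects {model.in_channels}-channel input, got {X.shape[1]}"
        )
    probs = []
    for start in range(0, len(X), batch_size):
        probs.append(model.predict_proba(X[start:start + batch_size])[:, 0])
    p = np.concatenate(probs)
    return p > threshold


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest 26-connected component of a binary 3D mask.

    Empty input yields empty output.  An exact size tie keeps the component
    containing the lexicographically smallest (z, y, x) voxel.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    lab, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 1:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = np.max(sizes)
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        flat = lab.ravel()
        first = {c: np.flatnonzero(flat == c)[0] for c in candidates}
        winner = min(candidates, key=lambda c: first[c])
    else:
        winner = candidates[0]
    return lab == winner


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, result: SegmenterResult, organ: str,
                    clip: ClipRange, uniform_size: tuple[int, int, int]) -> None:
    """Persist a trained segmenter with everything inference needs."""
    cfg = result.config
    np.savez(
        Path(path),
        variant=str(result.variant.value),
        organ=organ,
        clip_lo=clip.lo, clip_hi=clip.hi, clip_source=clip.source,
        uniform_size=np.asarray(uniform_size),
        seed=cfg.seed, widths=np.asarray(cfg.widths),
        threshold=cfg.threshold,
        **result.model.state_dict(),
    )


def load_checkpoint(path) -> tuple[UNet, ModelVariant, str, ClipRange,
                                   tuple[int, int, int], float]:
    with np.load(Path(path), allow_pickle=False) as data:
        variant = ModelVariant(str(data["variant"]))
        organ = str(data["organ"])
        clip = ClipRange(float(data["clip_lo"]), float(data["clip_hi"]),
                         organ, str(data["clip_source"]))
        uniform = tuple(int(v) for v in data["uniform_size"])
        widths = tuple(int(w) for w in data["widths"])
        cfg = TrainConfig(seed=int(data["seed"]), widths=widths,
                          threshold=float(data["threshold"]))
        model = build_model(variant, cfg)
        model.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
    return model, variant, organ, clip, uniform, cfg.threshold
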