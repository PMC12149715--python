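"""End-to-end orchestration: train detectors + segmenters, run inference.

Glue over the stage modules for cohort-level runs: build the DRR/box
training sets for an organ, fit the localization detectors and the
organ-specific segmenter, then localize → extract → segment → post-process
→ paste back on unseen volumes and score DSC.  All randomness derives from
one base seed, so a full simulate → train → infer → evaluate run is
reproducible bit for bit on CPU.

At training time, ROIs come from the reference masks (tight boxes fused and
margin-expanded exactly like predicted ones); at inference they come from
the trained detectors.  The head region at inference is taken from the
brainstem's own localization, mirroring its role as the head-area landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ORGAN_SPECS, Laterality, OrganGroup, OrganSpec
from .drr import BONE, WINDOWS, DRRImage, Plane, project
from .io_preproc import BodyMask, CTVolume, LabelSet, PatientMeta, derive_body_mask
from .localization import (
    Box2D,
    Detector,
    LocalizationResult,
    ROI3D,
    clip_to_max_size,
    expand_axial,
    fuse_body_boxes,
    fuse_head_boxes,
    head_region,
    localize_organ,
    oracle_detector,
    reference_box_from_mask,
    restricted_sagittal_drr,
    split_sagittal_drrs,
    _head_sagittal,
)
from .nets import DetectorConfig, HeatmapBoxDetector, train_detector
from .segmentation import (
    ClipRange,
    MiniCT,
    ModelVariant,
    SegmenterResult,
    TrainConfig,
    aggregate_clip_range,
    compute_clip_range,
    crop_mask_to_mini,
    extract_mini_ct,
    head_clip_range,
    largest_component,
    paste_back,
    predict_mask,
    train_segmenter,
)

Case = tuple[CTVolume, LabelSet, PatientMeta]


def _body_of(vol: CTVolume) -> BodyMask:
    return getattr(vol, "body", None) or derive_body_mask(vol)


def reference_roi(vol: CTVolume, labels: LabelSet, spec: OrganSpec,
                  head_z: tuple[int, int] | None = None) -> ROI3D:
    """ROI built from the reference mask through the same fusion + margins
    as a predicted one (oracle localization)."""
    dets = {p: oracle_detector(labels, spec.name, p, spec.box_scale)
            for p in Plane}
    res = localize_organ(vol, spec, dets, head_z=head_z, body=_body_of(vol))
    if res.status != "ok":
        raise ValueError(f"reference localization failed for {spec.name}")
    return res.roi


# ---------------------------------------------------------------------------
# detector training sets
# ---------------------------------------------------------------------------

def _in_image_box(mask: np.ndarray, image: DRRImage, scale: float) -> Box2D | None:
    box = reference_box_from_mask(mask, image.plane, scale)
    box = box.shifted(-image.origin[0], -image.origin[1])
    H, W = image.shape
    u = (max(0, box.u_range[0]), min(H, box.u_range[1]))
    v = (max(0, box.v_range[0]), min(W, box.v_range[1]))
    if u[0] >= u[1] or v[0] >= v[1]:
        return None
    return Box2D(image.plane, u, v)


def detector_training_set(
    cases: list[Case], spec: OrganSpec, plane: Plane
) -> tuple[list[DRRImage], list[Box2D]]:
    """(DRR, reference box) pairs for one organ and detection plane.

    Body organs: full coronal DRRs, and sagittal DRRs restricted to the
    organ's lateral extent.  Head organs: half (or full-width, for midline
    organs) sagittal DRRs of the head, and axial DRRs summed over the
    organ's superior-inferior extent; head boxes are scaled ×2.
    """
    w = WINDOWS[spec.window]
    images: list[DRRImage] = []
    boxes: list[Box2D] = []
    for vol, labels, _ in cases:
        if spec.name not in labels:
            continue
        mask = labels[spec.name]
        if spec.group == OrganGroup.body:
            if plane == Plane.coronal:
                img = project(vol, Plane.coronal, None, w)
            elif plane == Plane.sagittal:
                cor = reference_box_from_mask(mask, Plane.coronal)
                img = restricted_sagittal_drr(vol, cor.v_range, w)
            else:
                raise ValueError("body organs use coronal and sagittal planes")
        else:
            hz = head_region(vol, labels)
            if plane == Plane.sagittal:
                if spec.laterality == Laterality.none:
                    img = _head_sagittal(vol, hz, None, BONE)
                else:
                    left, right = split_sagittal_drrs(vol, hz, BONE, _body_of(vol))
                    img = left if spec.laterality == Laterality.left else right
            elif plane == Plane.axial:
                idx = np.argwhere(mask)
                z = (int(idx[:, 0].min()), int(idx[:, 0].max()) + 1)
                img = project(vol, Plane.axial, z, BONE)
            else:
                raise ValueError("head organs use sagittal and axial planes")
        box = _in_image_box(mask, img, spec.box_scale)
        if box is None:
            continue
        images.append(img)
        boxes.append(box)
    return images, boxes


# ---------------------------------------------------------------------------
# per-organ training
# ---------------------------------------------------------------------------

@dataclass
class TrainedOrgan:
    spec: OrganSpec
    detectors: dict[Plane, Detector]
    segmenter: SegmenterResult
    clip: ClipRange
    uniform_size: tuple[int, int, int]


def _round_up(n: int, f: int) -> int:
    return int(-(-n // f) * f)


def uniform_size_from_rois(rois: list[ROI3D], factor: int = 4,
                           slack: int = 2) -> tuple[int, int, int]:
    """Smallest padded size covering every training ROI, axial dims rounded
    up to the pooling factor."""
    z = max(r.size[0] for r in rois) + slack
    y = _round_up(max(r.size[1] for r in rois) + slack, factor)
    x = _round_up(max(r.size[2] for r in rois) + slack, factor)
    return (z, y, x)


def train_organ(
    cases: list[Case],
    organ: str,
    variant: ModelVariant | str = ModelVariant.basic_unet,
    seed: int = 0,
    det_epochs: int = 60,
    seg_cfg: TrainConfig | None = None,
    spec: OrganSpec | None = None,
) -> TrainedOrgan:
    """Fit the full two-stage model for one organ on a training cohort."""
    import copy

    spec = copy.copy(spec or ORGAN_SPECS[organ])  # crop size is calibrated below
    planes = ((Plane.coronal, Plane.sagittal) if spec.group == OrganGroup.body
              else (Plane.sagittal, Plane.axial))
    detectors: dict[Plane, Detector] = {}
    for i, plane in enumerate(planes):
        images, boxes = detector_training_set(cases, spec, plane)
        cfg = DetectorConfig(seed=seed * 101 + i, epochs=det_epochs)
        detectors[plane] = train_detector(images, boxes, cfg)

    # reference ROIs define the crop geometry and the clip range
    rois, minis, masks, clips = [], [], [], []
    for vol, labels, _ in cases:
        if organ not in labels:
            continue
        hz = head_region(vol, labels) if spec.group == OrganGroup.head else None
        rois.append((vol, labels, reference_roi(vol, labels, spec, hz)))
    uniform = uniform_size_from_rois([r for _, _, r in rois])
    if spec.max_crop_size is None:
        spec.max_crop_size = uniform
    if spec.group == OrganGroup.head:
        clip = head_clip_range(organ)
    else:
        clip = aggregate_clip_range(
            [compute_clip_range(vol, labels[organ], organ)
             for vol, labels, _ in rois])
    dataset = []
    for vol, labels, roi in rois:
        mini = extract_mini_ct(vol, roi, organ, uniform, clip)
        dataset.append((mini, crop_mask_to_mini(labels[organ], mini)))

    seg_cfg = seg_cfg or TrainConfig()
    seg_cfg.seed = seed * 101 + 7 if seg_cfg.seed == 0 else seg_cfg.seed
    seg = train_segmenter(variant, dataset, seg_cfg)
    return TrainedOrgan(spec, detectors, seg, clip, uniform)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer_organ(
    vol: CTVolume,
    trained: TrainedOrgan,
    head_z: tuple[int, int] | None = None,
) -> tuple[np.ndarray | None, LocalizationResult]:
    """Localize and segment one organ on an unseen volume.

    Returns (whole-body binary mask, localization record); the mask is None
    when localization reports "not found".
    """
    spec = trained.spec
    res = localize_organ(vol, spec, trained.detectors, head_z=head_z,
                         body=_body_of(vol))
    if res.status != "ok":
        return None, res
    roi = clip_to_max_size(res.roi, trained.uniform_size).clamped(vol.shape)
    mini = extract_mini_ct(vol, roi, spec.name, trained.uniform_size, trained.clip)
    pred = predict_mask(trained.segmenter.model, mini,
                        trained.segmenter.config.threshold,
                        trained.segmenter.variant)
    pred = largest_component(pred)
    return paste_back(pred, mini, vol.shape), res


def head_z_from_brainstem(vol: CTVolume,
                          brainstem: TrainedOrgan | None = None,
                          labels: LabelSet | None = None) -> tuple[int, int]:
    """Head region at inference: the localized brainstem's inferior border."""
    if brainstem is not None:
        res = localize_organ(vol, brainstem.spec, brainstem.detectors,
                             body=_body_of(vol))
        if res.status == "ok":
            return head_region(vol, brainstem_roi=res.roi)
    if labels is not None:
        return head_region(vol, labels)
    raise ValueError("brainstem model or labels required for the head region")


def evaluate_cohort(
    cases: list[Case],
    trained: dict[str, TrainedOrgan],
    model_name: str,
    brainstem: TrainedOrgan | None = None,
) -> pd.DataFrame:
    """DSC table for a set of trained organs on (typically held-out) cases."""
    rows = []
    need_head = any(t.spec.group == OrganGroup.head for t in trained.values())
    for vol, labels, meta in cases:
        hz = None
        if need_head:
            hz = head_z_from_brainstem(vol, brainstem, labels)
        for organ, t in trained.items():
            pred, res = infer_organ(
                vol, t, hz if t.spec.group == OrganGroup.head else None)
            from .evaluation import dsc as _dsc

            value = _dsc(labels[organ], pred) if pred is not None else 0.0
            rows.append((meta.id, organ, model_name, meta.cohort.value,
                         meta.age, value))
    from .evaluation import RECORD_COLUMNS

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
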