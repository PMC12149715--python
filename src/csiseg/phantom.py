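"""Synthetic whole-body pediatric CT phantoms with exact ground-truth masks.

Each phantom is a geometric caricature of a craniospinal-irradiation
planning CT: a soft-tissue body (elliptical torso stack, neck, head sphere)
in −1000 HU air, with analogs of the 18 organs at risk painted at
tissue-plausible HU so that the three contrast windows (lung / soft tissue /
bone) separate the intended structures:

* lungs ≈ −800 HU, trachea analog ≈ −900 HU (air tube) adjacent to an
  esophagus-like soft-tissue tube,
* vertebral column ≈ +700 HU with an embedded spinal-canal analog,
* kidneys ≈ 30 HU wrapped in a −100 HU fat rim whose thickness grows with
  age (the fat-plane cue radiologists use),
* a head with brain, brainstem, paired eyes (lenses inside), optic-nerve
  tubes meeting at a chiasm, and +500 HU cochlea analogs; an unlabeled
  skull shell and orbital sockets give the bone window a head outline.

A synthetic "age" covariate (years) scales every organ monotonically:
linear sizes are multiplied by ``0.70 + 0.30 * age / 18`` (linear in the
cube root of target volume).  All randomness (center jitter, noise) comes
from one seeded generator, so a fixed seed reproduces the phantom exactly;
the jitter draws happen before any age-dependent quantity, so the same seed
places organs identically at any age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preproc import (
    AIR_HU,
    BodyMask,
    BodyMaskSource,
    CTVolume,
    Cohort,
    LabelSet,
    PatientMeta,
)

#: default HU means, chosen so the standard windows separate the structures
DEFAULT_HU: dict[str, float] = {
    "body": 30.0,
    "lung": -800.0,
    "trachea": -900.0,
    "esophagus": 30.0,
    "vertebral_bodies": 700.0,
    "spinal_canal": 20.0,
    "kidney": 30.0,
    "fat_rim": -100.0,
    "brain": 35.0,
    "brainstem": 35.0,
    "eye": 20.0,
    "lens": 60.0,
    "optic_nerve": 40.0,
    "chiasm": 40.0,
    "cochlea": 500.0,
    "skull": 700.0,
}

HEAD_ORGANS = (
    "eye_l", "eye_r", "lens_l", "lens_r", "optic_nerve_l", "optic_nerve_r",
    "chiasm", "cochlea_l", "cochlea_r",
)


@dataclass
class PhantomSpec:
    age: float
    canvas: tuple[int, int, int] = (96, 96, 160)  # (Z, Y, X)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 5.0
    hu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    seed: int = 0
    id: str = "P000"
    cohort: Cohort = Cohort.train

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if any(c < 48 for c in self.canvas):
            raise ValueError("canvas too small for the phantom anatomy")


def age_scale(age: float) -> float:
    """Monotone linear-size multiplier for the age covariate."""
    return 0.70 + 0.30 * min(age, 18.0) / 18.0


# ---------------------------------------------------------------------------
# rasterization primitives (exact supports, evaluated on bounded subgrids)
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    lo = [max(0, int(np.floor(c - s - 1))) for c, s in zip(center, semiaxes)]
    hi = [min(n, int(np.ceil(c + s + 2))) for n, c, s in zip(shape, center, semiaxes)]
    if any(a >= b for a, b in zip(lo, hi)):
        return out
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = (((zz - center[0]) / semiaxes[0]) ** 2
         + ((yy - center[1]) / semiaxes[1]) ** 2
         + ((xx - center[2]) / semiaxes[2]) ** 2)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d <= 1.0
    return out


def _sphere(shape, center, r) -> np.ndarray:
    return _ellipsoid(shape, center, (r, r, r))


def _elliptic_cylinder(shape, z0, z1, cy, cx, ry, rx) -> np.ndarray:
    """Stack of identical axial ellipses over z in [z0, z1)."""
    out = np.zeros(shape, dtype=bool)
    z0, z1 = max(0, int(round(z0))), min(shape[0], int(round(z1)))
    if z0 >= z1:
        return out
    yy, xx = np.ogrid[:shape[1], :shape[2]]
    disk = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    out[z0:z1] = disk[None]
    return out


def _tube_z(shape, z0, z1, cy, cx, r) -> np.ndarray:
    return _elliptic_cylinder(shape, z0, z1, cy, cx, r, r)


def _capsule(shape, p0, p1, r, n_steps: int = 24) -> np.ndarray:
    """Union of spheres along the segment p0-p1 (a thick tube)."""
    out = np.zeros(shape, dtype=bool)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    if np.linalg.norm(p1 - p0) < 1e-9:
        return _sphere(shape, tuple(p0), r)
    for t in np.linspace(0.0, 1.0, n_steps):
        out |= _sphere(shape, tuple(p0 + t * (p1 - p0)), r)
    return out


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelSet, PatientMeta]:
    """Build one phantom: HU volume, exact organ masks, and patient metadata.

    Ground-truth masks overlap only for the declared containment pairs
    (lens inside eye, spinal canal inside vertebral bodies, brainstem and
    brain); every other pair is disjoint by construction.
    """
    Z, Y, X = spec.canvas
    shape = (Z, Y, X)
    rng = np.random.default_rng(spec.seed)
    m = age_scale(spec.age)
    mb = 0.85 + 0.15 * m / 1.0  # the body itself grows more slowly
    hu = spec.hu

    # jitter draws (age-independent: same seed -> same placement at any age)
    gy = rng.uniform(-2.0, 2.0)
    gx = rng.uniform(-3.0, 3.0)
    jit = {k: rng.uniform(-1.2, 1.2, size=3) for k in (
        "lung_l", "lung_r", "kidney_l", "kidney_r", "esophagus",
        "eye", "chiasm", "cochlea", "brain",
    )}

    cy, cx = Y / 2 + gy, X / 2 + gx
    r_head = 0.155 * Z          # base head radius; placement uses base geometry
    cz_head = 0.16 * Z
    head_c = (cz_head, cy, cx)

    # --- body support -----------------------------------------------------
    torso = _elliptic_cylinder(shape, 0.28 * Z, 0.97 * Z, cy, cx,
                               0.27 * Y * mb, 0.29 * X * mb)
    neck = _tube_z(shape, cz_head, 0.40 * Z, cy, cx, 0.50 * r_head)
    head = _sphere(shape, head_c, r_head)
    body = torso | neck | head

    vol = np.full(shape, AIR_HU, dtype=np.float32)
    vol[body] = hu["body"]

    # unlabeled skull shell (bone-window head outline)
    vol[head & ~_sphere(shape, head_c, 0.90 * r_head)] = hu["skull"]

    masks: dict[str, np.ndarray] = {}

    def paint(mask: np.ndarray, value: float, organ: str | None = None) -> None:
        vol[mask] = value
        if organ is not None:
            masks[organ] = mask

    # --- thorax / abdomen -------------------------------------------------
    for side, sx in (("l", -1), ("r", +1)):
        j = jit[f"lung_{side}"]
        c = (0.42 * Z + j[0], 0.48 * Y + gy + j[1], cx + sx * 0.14 * X + j[2])
        paint(_ellipsoid(shape, c, (0.10 * Z * m, 0.16 * Y * m, 0.09 * X * m)),
              hu["lung"], f"lung_{side}")

    paint(_tube_z(shape, 0.30 * Z, 0.42 * Z, 0.38 * Y + gy, cx, 0.022 * X),
          hu["trachea"])  # trachea analog, unlabeled
    je = jit["esophagus"]
    paint(_tube_z(shape, 0.30 * Z, 0.55 * Z, 0.46 * Y + gy + je[1] * 0.5,
                  cx + je[2], max(2.0, 0.018 * X * m)),
          hu["esophagus"], "esophagus")

    for side, sx in (("l", -1), ("r", +1)):
        j = jit[f"kidney_{side}"]
        c = (0.68 * Z + j[0], 0.55 * Y + gy + j[1], cx + sx * 0.11 * X + j[2])
        semi = (0.07 * Z * m, 0.09 * Y * m, 0.05 * X * m)
        rim_t = 1.0 + 1.5 * min(spec.age, 18.0) / 18.0  # fat plane thickens with age
        rim = _ellipsoid(shape, c, tuple(s + rim_t for s in semi))
        kidney = _ellipsoid(shape, c, semi)
        paint(rim & ~kidney, hu["fat_rim"])
        paint(kidney, hu["kidney"], f"kidney_{side}")

    vb = _tube_z(shape, 0.30 * Z, 0.93 * Z, 0.68 * Y + gy, cx, 0.045 * X * m)
    canal = _tube_z(shape, 0.30 * Z, 0.93 * Z, 0.68 * Y + gy, cx, 0.020 * X * m)
    canal &= vb
    paint(vb, hu["vertebral_bodies"], "vertebral_bodies")
    paint(canal, hu["spinal_canal"], "spinal_canal")  # contained in VB

    # --- head: compute all structures first, then paint -------------------
    ej = jit["eye"]
    eye_r = 0.26 * r_head * m
    eye_c, eye_m, lens_m = {}, {}, {}
    for side, sx in (("l", -1), ("r", +1)):
        c = (cz_head + 0.10 * r_head + ej[0] * 0.5,
             cy - 0.52 * r_head + ej[1] * 0.5,
             cx + sx * (0.40 * r_head + ej[2] * 0.3))
        eye_c[side] = c
        eye_m[side] = _sphere(shape, c, eye_r)
        lens_m[side] = _sphere(shape, (c[0], c[1] - 0.50 * eye_r, c[2]),
                               0.45 * eye_r) & eye_m[side]

    cj = jit["chiasm"]
    chi_r = 0.13 * r_head * m
    chi_c = (cz_head + 0.45 * r_head + cj[0] * 0.4,
             cy - 0.05 * r_head + cj[1] * 0.4, cx + cj[2] * 0.4)
    chiasm = _sphere(shape, chi_c, chi_r)

    # nerve endpoints are anchored with the *base* (age-18) eye/chiasm radii,
    # so the free length is age-independent and the voxel count grows with the
    # radius; carving (below) keeps the tube clear of the eye and chiasm
    nerve_r = max(1.05, 0.10 * r_head * m)
    nerves = {}
    for side in ("l", "r"):
        ec, cc = np.asarray(eye_c[side]), np.asarray(chi_c)
        u = (cc - ec) / np.linalg.norm(cc - ec)
        p0 = ec + u * (0.26 * r_head + nerve_r + 0.3)
        p1 = cc - u * (0.13 * r_head + nerve_r + 0.3)
        nerves[side] = _capsule(shape, p0, p1, nerve_r) & ~eye_m[side] & ~chiasm

    koj = jit["cochlea"]
    coch_m = {}
    for side, sx in (("l", -1), ("r", +1)):
        c = (cz_head + 0.30 * r_head + koj[0] * 0.4,
             cy + 0.15 * r_head + koj[1] * 0.4,
             cx + sx * (0.55 * r_head + koj[2] * 0.3))
        coch_m[side] = _sphere(shape, c, 0.13 * r_head * m)

    brainstem = _capsule(
        shape,
        (cz_head - 0.10 * r_head, cy + 0.22 * r_head, cx),
        (cz_head + 1.25 * r_head, cy + 0.22 * r_head, cx),
        0.16 * r_head * m,
    )
    bj = jit["brain"]
    brain = _sphere(
        shape,
        (cz_head - 0.25 * r_head + bj[0] * 0.3, cy + 0.10 * r_head + bj[1] * 0.3,
         cx + bj[2] * 0.3),
        0.62 * r_head * m,
    )

    # disjointness beyond the declared pairs: the small head structures carve
    # brain and brainstem; brain/brainstem may overlap each other (declared)
    small = (eye_m["l"] | eye_m["r"] | nerves["l"] | nerves["r"]
             | chiasm | coch_m["l"] | coch_m["r"])
    brain &= ~small
    brainstem &= ~small

    occupied = small | brain | brainstem
    for side in ("l", "r"):
        # unlabeled orbital socket: bone shell around each eye
        socket = (_sphere(shape, eye_c[side], 1.45 * eye_r)
                  & ~_sphere(shape, eye_c[side], 1.15 * eye_r))
        vol[socket & head & ~occupied] = hu["skull"]

    paint(brain, hu["brain"], "brain")
    paint(brainstem, hu["brainstem"], "brainstem")
    paint(chiasm, hu["chiasm"], "chiasm")
    for side in ("l", "r"):
        paint(nerves[side], hu["optic_nerve"], f"optic_nerve_{side}")
        paint(eye_m[side], hu["eye"], f"eye_{side}")
        paint(lens_m[side], hu["lens"], f"lens_{side}")
        paint(coch_m[side], hu["cochlea"], f"cochlea_{side}")

    # --- sanity: every organ rasterized, interior to canvas and body ------
    for organ, msk in masks.items():
        if not msk.any():
            raise ValueError(f"organ {organ} rasterized empty (canvas too small?)")
        idx = np.argwhere(msk)
        if (idx.min(axis=0) == 0).any() or (idx.max(axis=0) >= np.array(shape) - 1).any():
            raise ValueError(f"organ {organ} touches the canvas boundary")
        if not (msk <= body).all():
            raise ValueError(f"organ {organ} extends outside the body")

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    vol[~body] = AIR_HU  # noise only inside the body; background stays air

    ct = CTVolume(vol, spec.spacing, id=spec.id)
    ct.body = BodyMask(body, BodyMaskSource.provided)  # generator's exact support
    return ct, LabelSet(masks), PatientMeta(spec.id, spec.age, spec.cohort)


def generate_cohort(
    n: int,
    age_range: tuple[float, float] = (3.0, 18.0),
    seed: int = 0,
    canvas: tuple[int, int, int] = (96, 96, 160),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    noise_sd: float = 5.0,
    cohort: Cohort = Cohort.train,
    id_prefix: str = "P",
) -> list[tuple[CTVolume, LabelSet, PatientMeta]]:
    """Generate ``n`` phantoms with ages uniform in ``age_range``.

    Per-phantom seeds derive deterministically from ``seed``, so the whole
    cohort is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid age range {age_range}")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i in range(n):
        ps = PhantomSpec(
            age=float(ages[i]), canvas=canvas, spacing=spacing, noise_sd=noise_sd,
            seed=int(child_seeds[i]), id=f"{id_prefix}{i:03d}", cohort=cohort,
        )
        out.append(generate_phantom(ps))
    return out


def plant_dsc_trend(
    records: pd.DataFrame,
    organ: str,
    slope: float,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Inject an age-proportional DSC shift (plus noise) for one organ.

    The shift is ``slope * (age - min_age) / (max_age - min_age)`` plus
    Gaussian noise; results are clipped to [0, 1].  ``slope = 0`` leaves the
    distributional null untouched except for the noise term.
    """
    if organ not in set(records["organ"]):
        raise KeyError(f"unknown organ {organ!r}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    sel = (out["organ"] == organ).to_numpy()
    ages = out.loc[sel, "age"].to_numpy(dtype=float)
    span = ages.max() - ages.min()
    rel = (ages - ages.min()) / span if span > 0 else np.zeros_like(ages)
    shift = slope * rel + rng.normal(0.0, noise_sd, size=int(sel.sum()))
    out.loc[sel, "dsc"] = np.clip(out.loc[sel, "dsc"].to_numpy() + shift, 0.0, 1.0)
    return out
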