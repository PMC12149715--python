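# csiseg

Two-stage deep-learning auto-segmentation of organs at risk (OARs) on
whole-body CT, of the kind used for treatment planning of pediatric
craniospinal irradiation — with the evaluation metric and statistical
comparison machinery to judge it, exercised end to end on synthetic CT
phantoms with exact ground-truth masks.

**Who it is for:** medical-physics and imaging researchers who want a
CPU-friendly, institution-tunable alternative to monolithic whole-body
segmentation: many small organ-specific models instead of one large one.

## The method

Segmenting 18 structures from the brain to the kidneys directly on a
whole-body scan is dominated by class imbalance and normalization
conflicts. `csiseg` splits the task:

1. **Localization from digitally reconstructed radiographs (DRRs).**
   The HU grid is clamped to a contrast window (lung [−1500, 0], soft
   tissue [0, 50], bone [250, 3000] HU, or their 3-channel composite),
   summed along an axis, and normalized to 0–255. A single-class 2D
   detector predicts the organ's bounding box on two orthogonal DRRs and
   the boxes are fused into a 3D ROI: body organs go coronal → sagittal
   (the sagittal DRR is summed only over the coronal box's lateral
   extent), with axial margins of +20 px (lungs), +15 px (spine targets,
   kidneys, esophagus) or +10 px (brain, brainstem); small head organs go
   sagittal → axial on bone-window DRRs of the head region (bounded below
   by the brainstem), with left/right half images and ×2-scaled boxes.
   The detector is pluggable behind a two-method contract.
2. **Organ-specific U-Net segmentation.** The ROI is cropped into a
   mini-CT, clipped (body organs: 10th/90th HU percentiles inside the
   reference mask and a 2 mm rim, lowest-low/highest-high, aggregated per
   organ by the median; head organs: fixed 0–250 HU), normalized to
   [0, 1], padded to a uniform size, and segmented slice-by-slice by one
   of three variants: a basic U-Net, an attention U-Net (additive
   attention gates on the skips), or a 2.5D U-Net (3 input channels: the
   target axial slice between its neighbors). Augmentation: ±15°
   rotations and ±15% scaling with probability 0.5. Predictions are
   thresholded at 0.5, reduced to the largest 26-connected component, and
   pasted back into the whole-body frame.

Accuracy is scored with the 3D Dice similarity coefficient,
DSC = (2|A∩B| + ε)/(|A| + |B| + ε), ε = 1e-7. DSC tables feed a
statistics suite: Kruskal–Wallis across models (Holm-corrected across
organs) with Dunn's post-hoc pairwise tests; Mann–Kendall DSC-vs-age
trends with Benjamini–Hochberg FDR; Mann–Whitney U between the <10 and
≥10-year age groups and between validation and test cohorts.

The networks run on a compact numpy autodiff engine included in the
package (finite-difference-verified gradients, bit-reproducible CPU
training), so no GPU stack is required. A synthetic-phantom module
generates whole-body pediatric CT analogs — air background, soft-tissue
body, lungs, trachea + esophagus tubes, vertebral column with spinal
canal, kidneys with age-dependent fat rims, and a head with eyes, lenses,
optic nerves, chiasm, cochleae, brain and brainstem — with organ sizes
scaled monotonically by a synthetic age covariate, so the whole pipeline
is trainable and testable without patient data.

## Worked example

Train the two-stage model for the left-kidney analog on six phantoms and
score two held-out ones:

```python
from csiseg.phantom import generate_cohort
from csiseg.pipeline import train_organ, evaluate_cohort
from csiseg.segmentation import TrainConfig

cohort = generate_cohort(8, age_range=(8, 16), seed=3, canvas=(64, 64, 96))
train, test = cohort[:6], cohort[6:]

kidney = train_organ(train, "kidney_l", variant="basic_unet", seed=1,
                     det_epochs=60, seg_cfg=TrainConfig(seed=2, epochs=12))
table = evaluate_cohort(test, {"kidney_l": kidney}, model_name="basic_unet")
print(table.to_string(index=False))
print(f"\nmean held-out DSC: {table['dsc'].mean():.3f}")
```

```
patient    organ      model cohort       age      dsc
   P006 kidney_l basic_unet  train 11.832410 0.870013
   P007 kidney_l basic_unet  train  9.277911 0.836193

mean held-out DSC: 0.853
```

Each row is one held-out phantom: the detectors localized the kidney on
the coronal and restricted-sagittal DRRs, the fused ROI was cropped,
normalized and segmented, and the pasted-back mask was scored against the
exact ground truth. A DSC of 0.85 at this miniature budget (64×64×96
voxels, 6 training phantoms, 12 epochs) means the prediction overlaps the
reference on ~85% of the combined mask volume; the full-size runs in
`scripts/acceptance.py` reach ≈0.99. The same objects drive the
statistics, e.g. `csiseg.evaluation.summarize(table)` or, from a shell,

```bash
csiseg simulate --n 16 --ages 3,18 --seed 42 --out data/
csiseg preprocess --in data/ --out prep/ --canvas 160x96
csiseg stats --in dsc.tsv --out report/
```

(`csiseg --help` lists the full command set: simulate, preprocess, drr,
train-detector, localize, train-segmenter, infer, evaluate, stats.)

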