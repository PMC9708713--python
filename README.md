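# petdeblur

Brain FDG PET has limited spatial resolution: activity spills between
structures (the partial volume effect), thin cortical gray matter reads far
below its true uptake, and small hypometabolic lesions — such as the focal
cortical dysplasias sought in epilepsy presurgical workups — fade toward the
surrounding cortex.  `petdeblur` is a simulation-to-enhancement pipeline for
studying how much of that lost signal a learned deblurring model can
recover, built for researchers who want a fully synthetic, seeded,
CPU-friendly testbed:

1. **Synthetic anatomy** — nine-label digital head phantoms (GM, WM,
   cerebellar GM/WM, CSF, basal ganglia, bone, soft tissue, air) generated
   procedurally from nested ellipsoid shells, or read from user-supplied
   NIfTI segmentations.
2. **Ground-truth activity phantoms** — piecewise-constant FDG activity per
   label: GM = ratio x WM over the grid {1.2, ..., 6.6}, cerebellar GM =
   0.8 x GM, plus spherical GM-restricted lesions (1008/612/319 mm^3) at
   lesion/GM contrasts 0.6 and 0.3.
3. **Degradation** — an image-space standard-quality surrogate: resampling
   to the reconstruction grid, a Gaussian point-spread blur (scanner
   resolution ⊕ 4 mm post-filter in quadrature), and count-scaled Poisson
   noise.
4. **Enhancement network** — a 3D sequential dilated residual CNN
   (19 modules: 7x16 ch dilation 1, 6x32 ch dilation 2, 6x64 ch dilation 4;
   receptive field 89 voxels) with a global residual connection, implemented
   in pure numpy, trained with MAE loss and AdamW on 32^3 patch pairs and
   applied by overlapping-tile inference with windowed blending.
5. **Metrics** — masked PSNR / global SSIM / RMSE, per-ROI recovery
   coefficients `RC = mean(measured)/mean(truth)` and coefficients of
   variation, and per-lesion relative lesion activity
   `RLA = mean(lesioned)/mean(unlesioned)` with its relative error against
   the assigned contrast.

## Worked example

```python
import numpy as np
from dataclasses import replace
import petdeblur as pb

anatomy    = pb.generate_anatomy(pb.AnatomyConfig(seed=7))
assignment = pb.sample_activity_assignment(gm_wm_ratio=3.6,
                                           rng=np.random.default_rng(11))
gt  = pb.render_ground_truth(anatomy, assignment)
sq  = pb.degrade(gt, replace(pb.DegradationConfig(), seed=3))
rois   = pb.make_rois(anatomy)           # GM mask + radius-6-eroded WM mask
report = pb.evaluate_pair(gt.values, sq.values, rois)

center = pb.phantom.choose_lesion_center(anatomy, "right_frontal",
                                         np.random.default_rng(2))
roi     = pb.make_lesion_roi(anatomy, center, 1008.0)
lesioned = pb.insert_lesion(gt, roi, 0.3)
sq_les   = pb.degrade(lesioned, replace(pb.DegradationConfig(), seed=3))
```

prints, via the obvious formatting:

```
GM activity      : 12686 Bq/cm3 (ratio 3.6)
PSNR             : 10.20 dB
SSIM             : 0.318
RMSE             : 3922 Bq/cm3
GM RC            : 0.51
WM RC            : 1.00
GM COV           : 39.9 %
lesion volume    : 319 mm3
RLA ground truth : 0.30
RLA degraded     : 0.69
```

Reading: after degradation the thin cortical ribbon retains only ~51% of
its true activity while the deep (eroded) WM core is fully recovered —
the partial volume effect in one line — and a lesion inserted at 30% of GM
activity reads at 69%, i.e. most of its contrast is gone.  The realized
lesion (319 mm^3 sphere clipped to the ribbon) is far smaller than the
nominal sphere, as real cortical lesions are.

`pb.run_recovery_experiment(seed=1)` runs the scaled-down end-to-end study
(12 phantoms, 6 mm blur + mild noise, a small two-stage network, ≤ 30
epochs; several minutes on one CPU core).  At seed 1 it raises the held-out
GM RC from 0.77 to 0.89 and lowers mean lesion RLA from 0.82 to 0.76
(ground truth 0.45), with every individual lesion improving; see
`docs/methods.md` for what this does and does not demonstrate.

## Command line

```bash
petdeblur anatomy generate --n 10 --seed 1 --out anat/
petdeblur anatomy validate anat/anat00001.nii.gz
petdeblur phantom --anatomies anat/ --ratios 1.2,3.6,6.6 --out gt/ --seed 2
petdeblur degrade --manifest gt/ --config config.yaml --out sq/
petdeblur train --manifest sq/ --config config.yaml --out model.npz
petdeblur predict --ckpt model.npz --in sq/sq_x.nii.gz --out phq.nii.gz
petdeblur evaluate --ref gt/gt_x.nii.gz --test phq.nii.gz \
    --labels anat/anat00001.nii.gz --out report.csv
```

All stages read one YAML config (`petdeblur.config.default_config()` writes
a template) and are deterministic given their seeds.

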