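# Methods

`petdeblur` is a self-contained simulation-to-enhancement pipeline for brain
FDG PET: it builds labeled digital head phantoms, renders ground-truth
high-quality (GT-HQ) activity volumes, degrades them into standard-quality
(S-SQ) scans, trains a 3D dilated residual network to map S-SQ back to GT-HQ
(the predicted high-quality, P-HQ, volume), and quantifies what was
recovered.  This note documents the models, the defaults and why they were
chosen, the numerical choices, and what the desk-scale experiments do and do
not show.

## Anatomical model

Real studies segment T1-weighted MRI into nine tissue labels (cerebral gray
and white matter, cerebellar GM/WM, CSF, basal ganglia, bone, soft tissue,
air).  This package substitutes a procedural anatomy so the pipeline runs
from a seed with no data downloads: nested ellipsoid shells (scalp soft
tissue, skull, CSF) around a brain ellipsoid whose outer ribbon is cortical
GM (default thickness 3 mm) and whose interior is WM; a cerebellar ellipsoid
with its own GM ribbon and WM core sits posterior-inferiorly behind a CSF
gap, and basal-ganglia blobs are carved from deep WM.  Per-subject
morphological variability comes from seeded relative jitter (default 2%) of
the ellipsoid axes and ribbon thickness, so an anatomy is a pure function of
its configuration.  The label codes 0-8 (AIR, SOFT, BONE, CSF, GM, WM,
CEREB_GM, CEREB_WM, BG) are fixed and recorded in every NIfTI header the
package writes.  Users with real segmentations can bypass the generator via
`read_label_volume`.

Two discrete conventions are fixed so tests can be exact: connected
components use 26-connectivity, adjacency checks use 6-connectivity, and the
CSF shell is never jittered below two voxels so bone and cortex stay
separated.

## Activity model

A ground-truth phantom assigns one activity (Bq/cm^3) per label.  WM, CSF,
soft tissue and basal ganglia are drawn from independent lognormals
parameterized by (median, coefficient of variation); lognormals give
positive support and mild heavy tails.  The defaults (WM 3500, CSF 1200,
SOFT 1800, BG 11000 Bq/cm^3) are documented placeholders at clinically
plausible magnitudes standing in for population values estimated from a
normal-subject PET database that is not shipped; override them in config
for other tracers or cohorts.  Cerebral GM is exactly `ratio x WM` with the
ratio taken from the design grid {1.2, 1.8, ..., 6.6}; cerebellar GM is
exactly 80% of cerebral GM; cerebellar WM equals cerebral WM (a placeholder
for the same reason); bone and air carry no activity.  These exact
relations are what the recovery metrics are later measured against.

Hypometabolic lesions emulating focal cortical dysplasias are inserted as
the largest 26-connected component of a digital sphere (volumes 1008, 612,
319 mm^3; voxel-center-in-closed-ball rule) intersected with the cerebral GM
mask, with lesion activity set to `contrast x GM` at contrasts 0.6 and 0.3
(0.3 is the stronger, more conspicuous lesion).  Because the sphere is
clipped by the thin cortical ribbon, realized lesion volumes are far smaller
than the sphere volumes — tens to a few hundred mm^3 — which is the size
regime that makes such lesions hard to see.  Lesion centers are drawn,
seeded, from GM voxels in lobe-like octants of the ribbon (right-frontal and
left-temporal by default), a reproducible stand-in for manual placement.

## Degradation model

Monte-Carlo simulation of the acquisition plus iterative reconstruction is
deliberately replaced by an image-space surrogate; this is the package's
central simplification.  The pipeline is: trilinear resampling to the
reconstruction grid (default 2.04 x 2.04 x 2.03 mm); one Gaussian blur at
the quadrature-combined FWHM of the scanner resolution (4.3 mm) and the
post-reconstruction filter (4 mm) — combining them once exploits the
Gaussian semigroup and avoids double resampling; optional scaled Poisson
noise, `v -> Poisson(v x count_scale) / count_scale`; trilinear resampling
back to the source grid; clipping negatives.  Convolution is zero-padded,
consistent with the air background.  Attenuation, scatter, randoms,
dead-time and decay are out of scope: the network and the metrics consume
images only, and blur plus count noise expose the same controllable
image-level degradations.

`count_scale` has no physical derivation here (in a real acquisition the
noise level emerges from the count budget); its default 3e-4 was set with
`calibrate_count_scale` so the default phantom's GM ROI shows a COV near
39%, a realistic standard-quality magnitude.  The calibration helper is
empirical — it measures the noise-variance slope from one probe simulation —
because resampling between grids smooths the noise in a way a closed-form
Poisson model misses.

## Network

A sequential, fully convolutional 3D residual network: 19 modules of
3x3x3 convolution + batch normalization + ReLU, in three stages — seven
modules of 16 channels at dilation 1, six of 32 at dilation 2, six of 64 at
dilation 4 — followed by a linear 3x3x3 output convolution to one channel.
Zero padding equal to the dilation preserves spatial shape everywhere, and
the dilation schedule widens the theoretical receptive field to 89 voxels
per axis (the field grows by 2d per conv, plus 2 for the output module)
without any down/upsampling.  Two topology choices are exposed as flags
because reasonable variants exist: a single global residual connection (the
network predicts a correction added to its input) and a zero-initialized
output convolution, so an untrained network is exactly the identity and
training starts from the degraded image rather than from noise.  The output
module is linear (no normalization or activation): this is a regression
head.

The implementation is numpy throughout: convolutions are one small
BLAS GEMM per kernel tap, with the contiguous tap slices cached between the
forward and backward pass (memory traded for memory bandwidth, which
dominates on one core); batch normalization keeps float64 running statistics
that are frozen in eval mode, so inference is deterministic.  Parameters are
float32 by default; float64 is available where tests need tight tolerances.
Gradients are verified against central finite differences in the test suite.

## Training and inference

Volumes are standardized by the mean of each pair's standard-quality image
("mean" is the arithmetic mean over all voxels including background — the
background fraction is stable within this pipeline, but users cropping
volumes should know the factor depends on it).  The ground truth shares its
pair's factor, so the learned mapping is scale-free; factors are stored and
re-applied to predictions before any quantitative analysis.  Training
minimizes mean absolute error over randomly sampled aligned patch pairs
(default 32^3, twenty per volume, resampled each epoch from a per-epoch
seed; centers are restricted to positive ground-truth voxels because
all-background patches carry no gradient).  The optimizer is AdamW at
learning rate 1e-4, reduced by 10x after 10 validation epochs without a new
minimum (improvement threshold 1e-6 relative); training stops at 200 epochs
or after 60 stagnant epochs, and the best-validation parameters are
returned.  The split is by volume (80/10/10), never by patch.  Validation
patches are drawn once so the early-stopping monitor is a fixed quantity.

Whole volumes are predicted by overlapping tiles (default 32^3 patches,
stride 8), blended with per-voxel normalized Hann-window weights (uniform
available).  Two refinements make tiling faithful: edge tiles are clamped
inside the volume rather than padded, and every patch face that does not
touch the volume boundary has a margin excluded from blending —
`min(receptive half-width, (patch - stride)/2)` — so each voxel is predicted
only from patches giving it full spatial context.  When the margin covers
the receptive field this makes tiled prediction agree with a single
full-volume forward pass to float precision; for the full-size network (half
width 44) the agreement is approximate but seam artifacts remain suppressed.
Because batch-norm statistics are computed on the normalized scale, a
full-volume oracle must also run on that scale.

## Metrics

All metrics are masked.  PSNR, SSIM and RMSE run over the brain mask
(GM ∪ WM ∪ cerebellar GM/WM ∪ BG ∪ CSF) by default, with an explicit mask
override.  SSIM is the single global form — one statistic from mask-wide
means, variances and covariance with absolute constants c1 = 0.01,
c2 = 0.03 — not a sliding-window mean; moments are population (divide by N).
PSNR is `20 log10(Max(reference)/RMSE)` by default; a `denominator="mse"`
switch computes the Max/MSE variant for comparison with sources that print
it that way.  Identical images return an `inf` sentinel rather than a cap.

Recovery coefficient: ROI mean of the measured image over the ground-truth
ROI mean (1 = perfect quantification).  The WM ROI is the WM mask eroded by
a Euclidean ball of radius 6 voxels (voxel-center rule, computed by
distance transform, exact per the brute-force oracle), giving a conservative
core free of GM spill-in.  COV: 100 x population std / mean in an ROI.
Relative lesion activity (RLA): lesion-ROI mean of a lesioned image over
the same ROI in its matched unlesioned image; lower RLA = more conspicuous
lesion; the ground-truth RLA equals the assigned contrast by construction.
Relative RLA error is `(measured - truth)/truth` (an absolute-value variant
is a flag).

## Desk-scale experiment

`run_recovery_experiment` is the package's own scaled-down analogue of
training on thousands of full-size simulated volumes: 12 phantoms on 96^3
1 mm grids (ratios cycling through the design grid), degradation reduced to
a 6 mm blur on the native grid plus mild count noise (count_scale 8e-3), a
two-stage network ((3, 8, 1), (2, 16, 2); receptive field 17), 20^3 training
patches (6 per volume, batch 10), AdamW at 1e-3 — a learning rate suited to
the small network and short schedule — for at most 30 epochs, with
inference tiled at 32/16.  Problem sizes were chosen so the whole experiment
runs in minutes on one CPU core.  On the held-out phantom the experiment
measures GM/WM recovery before and after enhancement and, on lesioned
variants of the same anatomy (every sphere volume x contrast, two sites,
noise paired with the unlesioned scan so RLA isolates the lesion), the
relative lesion activity.

Typical behavior (seed 1): GM RC rises from ~0.77 (S-SQ) to ~0.89 (P-HQ),
WM RC stays near 1, and mean RLA falls from ~0.82 toward the ground truth
0.45, with every individual lesion improving.  What this shows is the
direction and mechanism — a residual network trained only on simulated pairs
undoes a known partial-volume degradation and restores lesion contrast.
What it does not show: full-scale magnitudes (those depend on Monte-Carlo
physics, reconstruction, 2100-volume training and human readers), robustness
across scanners, or behavior on real data; the synthetic anatomy also lacks
gyral folding, so the GM ribbon here is geometrically simpler than a real
cortex and recovery numbers are not comparable to clinical ones.

## Known limitations

- The degradation is an image-space surrogate; it reproduces blur and
  count-dependent noise but not sinogram-domain effects, and the noise is
  white before resampling whereas reconstructed PET noise is correlated.
- Activity distributions and cerebellar WM activity are placeholders, not
  population estimates.
- The numpy network trains small models at desk scale; it is not a
  framework for full-size (19-module, 2100-volume) training runs.
- Ellipsoid-shell anatomy has no sulci/gyri; lesion ROIs are realistic in
  volume but not in shape complexity.
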