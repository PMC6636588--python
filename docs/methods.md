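# Methods

This note documents the models, parameters, and numerical choices behind
`qmlm`, and what the synthetic phantoms do and do not establish about real
data.

## Quantitative maps

**T2 relaxometry.** The multi-echo signal is modeled as mono-exponential,
`S(TE) = S0·exp(−TE/T2)`, and fitted per voxel by unweighted ordinary least
squares of `ln S` on TE (`T2 = −1/slope`, `S0 = exp(intercept)`).  The
log-linear estimator is used deliberately — it is the standard clinical
postprocessing choice and is exact on noiseless data — rather than a
weighted or nonlinear fit; at the SNRs exercised here the difference is well
inside the between-subject variability.  Voxels with any nonpositive echo
sample, or with slope ≥ 0 (no decay), are cleared from the validity mask and
set to the sentinel −1, never clamped: fit failures stay visible and are
excluded from cohort statistics as NaN by the measure layer.  The
non-decay test uses `slope < −1e-12` so that exactly constant signals, whose
OLS slope is a −1e-17-scale rounding residue, are correctly rejected (a
rejected fit at that slope would otherwise claim a 10^12 ms T2).

**MTR.** `MTR = (MT_off − MT_on)/MT_off × 100` per voxel; voxels with
`MT_off ≤ 0` are undefined and dropped from the validity mask.

**Gray–white junction (WGJS).** Per subject: (1) binary GM and WM masks at
tissue probability > 0.9; (2) T1-intensity mean/SD over each mask; (3) a
binary junction mask of brain voxels with intensity in
`[mean_GM − SD_GM, mean_WM + SD_WM]`; (4) convolution with a unitary 5×5×5
kernel (zero-padded), yielding per-voxel junction counts in [0, 125].  The
interval statistics use the subject's own raw T1 intensities: per-subject
normalization makes the rule invariant to global intensity scaling, so no
separate intensity normalization step is required.  Zero padding at the
borders is acceptable because the junction mask never touches the grid
border on brain-shaped inputs.

**MD and cortical thickness** are consumed as precomputed scalar maps
(scanner- and surface-pipeline-derived, respectively) and validated for
grid alignment and non-negativity.  Thickness is represented as a voxelwise
scalar supported on the GM ribbon — not a surface mesh — so the shared voxel
engine can process it; off-ribbon voxels are zero for every subject, have
zero cohort SD, and are therefore automatically excluded from testing.

## Detection engine

The single-subject statistic is the plain z-score against the control
cohort, `z = (x − mean)/sd` (SD with ddof = 1).  A small-cohort variant that
inflates the SD by `sqrt(1 + 1/n)` (Crawford–Howell-style) is available as
a flag but is off by default.  Undefined voxels (zero cohort SD, failed
fits) are NaN and never counted as tests.

Smoothing is Gaussian with FWHM given in mm
(`sigma = FWHM/(2·sqrt(2·ln 2))` per axis, converted by voxel size) and
mask-renormalized: the result is `smooth(x·m)/smooth(m)` inside the mask, so
out-of-brain zeros do not dilute edge voxels and constants are preserved.
Non-finite voxels are treated as missing data in the same renormalization —
excluded from the weighting and given a neighborhood-interpolated value.
This matters in practice: without it one failed-fit NaN voxel propagates
through the convolution and poisons the entire smoothed map.

Significance modes:

- *uncorrected*: `p ≤ α` per voxel (two-sided by default — abnormality may
  be an increase or a decrease);
- *FDR*: Benjamini–Hochberg over the tested voxels (largest sorted `p_(i)`
  with `p_(i) ≤ i·q/m`; 0.0 when nothing passes);
- *FWE*: Bonferroni, `p ≤ α/m` over the tested voxels.  Random-field-theory
  FWE was intentionally not implemented: Bonferroni is conservative,
  assumption-free and exactly reproducible, which suits a calibration loop
  whose job is to bound the subject-level false-positive rate anyway.  A
  max-statistic permutation alternative was considered and left out; the
  Bonferroni route covers every supported analysis path.

Surviving voxels are grouped by 26-connectivity (configurable to 6/18; the
choice is recorded in results), and clusters below the extent threshold
`k` are discarded.  The parenchyma filter then removes clusters whose
|z|-peak lies in an excluded atlas label (background, CSF, ventricles,
brainstem, cerebellum) or — when the atlas carries a cortical GM mask —
farther than 5 mm (configurable) from cortical gray matter, implemented via
a Euclidean distance transform in mm.  When no GM mask is available the
distance rule is skipped and only label exclusion applies.

**Monotonicity, precisely.** Tightening thresholds can never create
detections, but the number of clusters is monotone only in `k`.  Lowering
the p-threshold shrinks the suprathreshold voxel set (nesting) and can
*split* one large component into several surviving fragments, so cluster
counts may rise even as total detected volume falls.  The invariants that
hold, and that the tests assert, are: voxel-set nesting under decreasing p;
the largest surviving cluster never grows; whether a subject is flagged
(any cluster ≥ k) is monotone in both p and k; and cluster count is
non-increasing in k.

## False-positive calibration

Each control is compared against the remaining n−1 controls with the full
chain (smooth → z → threshold → parenchyma filter; the same filter used for
patients, so calibration matches deployment).  The leave-one-out mean and SD
are computed by rank-one updates of the cohort sums, which makes the 30×
re-estimation cheap; n ≥ 3 is required since the leave-one-out SD uses
ddof = 1.  A control whose leave-one-out z is undefined everywhere (a
zero-variance cohort) is simply not flagged.

`calibrate_fp` evaluates every grid point and, among points whose flagged
fraction does not exceed the target (default 0.10 — at most 3 of 30
controls), returns the one with the smallest cluster extent; ties break
toward the less restrictive p-setting (mode order uncorrected < FDR < FWE,
then larger p), then grid order — the p-ordering is an implementation choice
for determinism.  If no point is admissible the minimum-FP point is returned
flagged `admissible=False`.  The default grid crosses the two p-settings
used in practice (uncorrected 0.001, FWE 0.05) with cluster extents
{10, 30, 55} at 6 mm smoothing.  The target rate is a parameter rather than
a hard-coded narrative, and the cohort size actually supplied is recorded in
the result.

A note on tails: the leave-one-out z of a control is approximately
t-distributed (≈ t with n−2 degrees of freedom, scaled), so at n = 30 its
tails are noticeably heavier than the nominal normal — uncorrected
p ≤ 0.001 genuinely flags more voxels than 0.1% in null cohorts.  This is a
feature of the calibration design, not a defect: the leave-one-out loop
measures the realized subject-level rate and tightens the cluster extent or
p-mode until the budget holds, absorbing exactly this kind of
miscalibration.

## Concordance scoring

Clusters are localized to the (lobe, side) of their |z|-peak voxel, the
standard reporting convention; when the peak sits on excluded tissue the
majority parenchymal label over the cluster decides (ties toward the more
frequent, then smaller label).  A cluster is concordant when its region
matches any hypothesized EZ region; regional hypotheses spanning several
lobes are represented as region sets, and an unlateralized region matches
either side — an explicit, logged choice for electroclinical hypotheses that
regionalize without lateralizing.  Subject calls: `concordant` (≥1
concordant cluster), `discordant_only`, `no_findings`, `NA_NSLF`.

## Synthetic phantoms

Geometry is a set of concentric smoothed ellipsoids in a 48×56×48 grid of
3 mm isotropic voxels: a CSF rim, a GM ribbon, a WM core, central
ventricles, and a brainstem/cerebellum block; a quadrant rule over the
anterior–posterior and superior–inferior axes assigns frontal / parietal /
temporal / occipital × left / right labels to the cerebral parenchyma.
Tissue probability maps are lightly smoothed class indicators.  The
geometry is deterministic and shared by a cohort (a common space), so no
spatial normalization step is simulated.

Per subject and per channel, each tissue parameter map is
`mean_tissue + g·sd_tissue`, where `g` is one unit-variance Gaussian random
field (white noise smoothed to 18 mm FWHM, empirically renormalized) —
the simplest structure giving nonzero, spatially smooth cohort SD.
Channels then follow their forward models (mono-exponential echoes at
TE = 20…100 ms; `MT_on = MT_off·(1 − saturation_fraction)`; direct maps for
MD, thickness, T1w) plus additive Gaussian noise.  Rician noise is available
as a flag; at the simulated SNRs (>100 on the echo channel) the Gaussian
approximation is accurate.  Tissue statistics are literature-typical 3T
values chosen once (GM/WM/CSF T2 = 100/80/500 ± 5/4/25 ms; MD = 0.85/0.75/3.0
×10⁻³ mm²/s; MT saturation 0.30/0.45/0.05; GM thickness 2.5 ± 0.25 mm;
T1w 400/600/150), since acquisition protocols do not pin down map-level
intensity statistics.

Randomness is structured for reproducibility: subject *i* of a cohort
depends only on `seed + i` (so growing a cohort never changes existing
subjects), and each channel draws from its own substream (so generating a
subset of channels reproduces the full run bit for bit).  Lesions are
spheres in mm; insertion offsets the *pre-noise* parameter map of exactly
one channel by `delta` × the local between-subject SD and re-derives that
channel with the subject's frozen noise realization, leaving every other
channel bit-identical.

**What the phantoms do not emulate** — and hence what passing tests do not
show about real data: cortical folding (junction geometry is far simpler
than real gyri, so WGJS sensitivity on phantoms does not transfer
quantitatively); registration/segmentation error (maps are generated in a
common space, while real pipelines inherit normalization artifacts,
especially for low-resolution maps); scanner artifacts (bias fields,
motion, k-space effects); lesions as pure additive offsets (real FCD alters
texture and geometry jointly across channels); and age/sex covariate
structure, which the group model deliberately omits.

## Problem sizes and runtime defaults

The end-to-end studies use the full 48×56×48 grid: false-positive
calibration on 10 independent 30-control cohorts and lesion recovery
(5-SD, ~150-voxel cortical lesion, 20 controls, uncorrected p ≤ 0.001,
k = 30) on 20 independent cohorts; each cohort takes a few seconds on one
CPU thanks to the rank-one leave-one-out updates.  Unit tests use 24×28×24
phantoms and ≤16³ random grids for the brute-force oracle comparisons
(flood-fill clustering, box convolution, junction interval, BH cutoff,
distance filter), which are checked bit-exactly.

## Known limitations

- Bonferroni FWE is conservative relative to random-field or permutation
  FWE; with calibration in the loop this costs sensitivity at a given
  nominal α but never false-positive control.
- The plain-z statistic ignores cohort-size uncertainty; for n ≲ 15 the
  `sqrt(1 + 1/n)` variant is recommended.
- Lobe assignment by peak voxel can misattribute clusters straddling lobe
  boundaries; the majority-fallback applies only when the peak is on
  excluded tissue.
- The phantom's ellipsoidal geometry makes the parenchyma filter's
  distance-to-cortex rule stricter than on real anatomy (the WM core is
  deep), so lesions are inserted at the cortical ribbon in the simulated
  studies — consistent with the FCD target.
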