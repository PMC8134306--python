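# Methods

## Problem and scope

`seegbend` models the deviation of SEEG depth electrodes from their
planned straight (bolt-axis) trajectories. The package covers: the label
algebra of electrode bending; a synthetic phantom generator (brain-like
labeled volumes plus bent electrodes); two per-point regression networks
with their training protocol; iterative rollout inference with
Monte-Carlo-dropout uncertainty; and a stratified hold-out + k-fold
evaluation harness. Image-to-image registration, brain parcellation,
skull stripping and contact detection from CT are out of scope — the
package consumes their products (co-registered intensity and tissue-label
volumes, electrode point lists) and only *applies* given affine
transforms.

## Trajectories and labels

Trajectories are ordered 3D world-mm points at a nominal 1 mm spacing.
Irregular input point sets (entry, contacts, target) are resampled with a
shape-preserving piecewise-cubic Hermite (PCHIP) curve parametrized by
cumulative chord length. Because a curve's total arc length L is
generally not an integer number of millimetres, the samples are placed at
uniform arc-length steps h = L / round(L), so the first and last samples
coincide exactly with the first and last control points and all gaps are
mutually equal (within 0.01 mm); h deviates from 1 mm by at most
0.5/round(L), under 5% for clinically relevant lengths and 0 for the
integer-length trajectories the phantom generator produces. Parameter
targets are found by inverting a dense (16 384-sample) arc-length table
with a Newton correction using the analytic curve speed. Consecutive
duplicate control points (e.g. coincident contact detections) are dropped
before fitting.

For interior index i (1 ≤ i ≤ I−2):

    v̂_i = (x_i − x_{i−1}) / |x_i − x_{i−1}|      travel direction
    x_p  = x_i + 1·v̂_i                            straight-ahead projection
    lu_i = x_{i+1} − x_p                           local displacement (mm)
    êb_i = (x_{i+1} − x_i) / |x_{i+1} − x_i|       bending direction
    gu_i = x_i − r_i                               global displacement vs. the
                                                   index-matched rigid point

For exactly unit-spaced trajectories v̂ + lu = êb; the test suite asserts
this to 1e−9 on the generator's output, whose implanted paths advance in
exact 1 mm steps. Labels at i = 0 are undefined (no predecessor); rollout
uses the bolt direction there. When a network regresses êb, its output is
renormalized to unit length before stepping, since a regressor's output
is not norm-constrained.

MSE_i between two index-matched trajectories is the mean over points of
the squared Euclidean distance, in mm²; the 1 mm² threshold is used for
reporting. The training/evaluation label error MSE_t averages squared
error over samples *and* the three components, so values are displayed
×10³.

## Phantom generator

The generator emulates the structure the models assume rather than
anatomical realism: a 96³ voxel, 1 mm isotropic head with an ellipsoidal
cortex shell (semi-axes 42/40/38 voxels), a white-matter interior
(33/31/29) and 2–4 deep-grey ellipsoidal blobs inside it. The T1-like
intensity is the per-tissue mean (0.45 cortex, 0.75 white, 0.55 deep
grey) times a smooth multiplicative bias field (±5%, cubic-interpolated
4³ noise) plus Gaussian noise (sd 0.02), clipped to [0, 1]. All draws
come from a per-case stream spawned from the master seed, so cohorts are
bitwise reproducible.

Electrode insertion advances the tip 1 mm per step from a cortex-surface
entry along an inward bolt direction. Three mechanisms produce the
implanted path:

* the first 5 steps are perfectly straight (the guide bolt constrains
  the first millimetres; this also makes the 5-point rollout seed exact);
* each later step the direction receives an angular random walk of sd
  0.15°;
* when the tissue code under the tip changes, a total deflection angle
  θ ~ N(4°, 1.5°) is sampled and develops as a ramp over 4 subsequent
  steps (θ/4 per step) about the axis v̂ × n̂, where n̂ is the interface
  normal estimated from a σ = 2 voxel Gaussian smoothing of the tissue
  codes. The electrode thus bends smoothly, in the plane of incidence,
  toward the deeper tissue — a deterministic function of the local image
  and direction, which is what makes the synthetic bending learnable by
  an image-based model; a single-step "kink" variant
  (`deflection_ramp_steps=1`) is available but is much harder to regress
  at voxel resolution.

Electrode metadata (six anatomical strata, entry lobe, target region,
stylet use) is sampled first — group proportions default to the cohort
imbalance pattern (tg largest, ifog/apcg smallest) — and realized
geometrically: entry lobes map to 72° azimuth sectors on the upper
ellipsoid, insula/cingulum targets lie near the volume centre, others at
mid-depth. The deterministic rule `group_from_metadata` (temporal → tg,
parietal/occipital → po, cingulum target → apcg, insula target → ifog,
frontal-to-frontal → sfg, other anterior → mfg) keeps labels consistent
and lets the stratifier validate them.

What the phantom does **not** emulate: gyral/sulcal geometry, partial
volume effects, scanner artifacts, stylet-dependent mechanics, brain
shift, or spatially varying electrode stiffness. Passing tests therefore
show the pipeline is correct and that the models can learn
interface-driven bending from images; they do not certify accuracy on
patient data.

## Features (HcF input)

The authentic line-item roster behind the 96-feature count is not
reproducible from public sources, so the package freezes its own
documented roster, schema `v1`: 78 continuous features in the four named
categories — implantation (12: depth/fraction along, angles and
components relative to the bolt frame, lateral offset, distances to entry
and rigid target), bending (20: trailing 5-point histories of |lu|, |gu|
and step angles, cumulative curvature, running mean/max), structure (34:
ray-marched distances to tissue interfaces and classes, occupancy
fractions and intensity statistics of 3³/5³ neighbourhoods, codes ahead
and behind along v̂), collision (12: distances to the brain and volume
boundaries, interface-normal alignment, steps since the last crossing) —
plus 18 one-hot dims (stylet 3, tissue region at point 3, entry lobe 5,
target region 7). Features use only the history up to the current point,
never the regression target, so training-set construction and
predicted-history rollout share one code path; early indices zero-pad
their histories. Continuous features are z-scored with statistics fitted
on each fold's training split only (constant features map to 0); one-hot
entries pass through.

## Networks and training

Both networks are implemented in numpy with hand-written reverse-mode
gradients (verified against central finite differences in the test
suite); the footprint (≤ ~17k parameters) makes CPU training practical.

*HcF*: dense 96→5, PReLU, then three blocks (dense 5→5, PReLU, dropout),
then dense 5→3 — 597 parameters. The published description reads
literally as a bare PReLU on the raw features; a 96→5 input stage is used
so the stated 5-unit topology is actually reachable.

*E2E*: direction branch dense 3→5 + ReLU; image branch 3D conv 1→8
channels, 3×3×3 kernel, zero padding, leaky ReLU, 2×2×2 max pool (9³ →
4³), flatten; concatenated into dense 32 and dense 8 blocks (leaky ReLU,
1D batch norm, dropout) and a final dense 3. The conv channel count is
not pinned by the architecture description; 8 is the default (16 was
ablated with no measurable gain).

Training: Adam with coupled L2 weight decay 10⁻³, lr 10⁻³, batch 64,
200 epochs (protocol default), validation every 5 epochs, checkpoint at
the best validation loss. The learning rate drops ×0.1 (patience 10,
min 10⁻⁶) when the *deterministic* end-of-epoch training loss plateaus:
monitoring the stochastic batch-mean loss lets dropout noise fake an
unbeatable best and triggers premature drops. The output head is
initialized at 1% of He scale so a regressor of millimetre-scale labels
starts near the zero map. Dropout rate 0.1 everywhere, matching the MC
inference rate.

MC-dropout inference runs T = 200 stochastic passes at p = 0.1 with
batch-norm statistics frozen (only dropout masks are resampled) and
reports the per-component mean and population variance. p = 0 reproduces
the deterministic pass exactly; the SD of the MC mean scales as 1/√T.

## Rollout

From the first five rigid points, each iteration computes v̂ from the
last two predicted points, builds the model input at the tip (feature
vector from the *predicted* history, or direction + 9³ window centred on
the tip's nearest voxel; tissue windows are scaled by the fixed constant
1/3 to preserve categorical meaning), predicts the label, and advances
1 mm (lu: x + v̂ + lu; êb: x + unit(êb)). Rollout depth defaults to the
implanted trajectory's point count so MSE_i is index-matched. A tip
leaving the volume zero-pads its window, logs the event and continues.
Direct mode is bit-reproducible; MC mode is reproducible given the MC
seed.

## Evaluation protocol

Splits are by case (all electrodes of a patient stay together):
floor(10%) of cases form the hold-out (86 → 8, matching the published
protocol), the rest are shuffled into k near-equal folds. Per fold, a
model trains on the other folds and validates on the held fold; MSE_t is
reported on the hold-out point set per fold (mean and SD across folds,
optionally with MC-averaged predictions). Every fold model then infers
every hold-out electrode — n_electrodes × k rollouts — and the harness
reports per-group/per-fold MSE_i distributions, the fraction ≤ 1 mm², and
the paired per-electrode comparison against the rigid baseline. The
hold-out is shared across groups (not re-drawn per group), and leakage is
prevented structurally: training sets, normalizer fits and validation
sets are assembled from fold case-id lists that the tests audit against
the hold-out.

## Scaled study conditions

The package's end-to-end demonstration (`run_trajectory_validation_study`
and `scripts/acceptance.py`) uses 40 cases × 8 electrodes (~320
electrodes, mirroring the ~10 electrodes/case ratio of a clinical
cohort at half the case count), 3 folds, 50 epochs, pooled across groups
— per-group folds would be too thin at this cohort size; the per-group
path is exercised at unit-test scale. On one CPU the study takes
~10 minutes. Under these conditions the rigid baseline's MSE_i
distribution straddles the 1 mm² threshold (as in the clinical regime,
where per-group rigid-vs-implanted MSEs of 0.1–0.3 mm² are typical), the
trained E2E-tissue lu models improve the majority of hold-out electrodes
(negative paired median), and lu regression outperforms êb regression at
rollout by an order of magnitude — êb errors compound because every
mispredicted unit step carries full length.

## Numerical choices and degenerate inputs

Zero-norm vectors (directions, êb labels) raise; coincident consecutive
points raise; affines must be invertible with a (0,0,0,1) bottom row;
normalizers refuse to transform before fitting; empty datasets refuse to
train; a non-finite training loss aborts with diagnostics. Nearest-voxel
(not trilinear) sampling is used wherever tissue codes are read, keeping
them categorical. All randomness flows through `numpy.random.Generator`
streams spawned from a single seed per entry point.

## Known limitations

Phantom bending is a three-mechanism caricature; real electrodes also
bend from stylet withdrawal, vessel avoidance and tissue anisotropy.
The feature roster is a documented stand-in, not the original list.
The E2E model captures only part of the synthetic deflection signal
(direction recovery at interfaces is the hard part at voxel resolution),
so rollout gains over the rigid baseline are modest for mildly bent
electrodes and largest in the bent tail of the distribution — mirroring
the qualitative behaviour reported for the clinical cohort, where
predictions sometimes under-bend at depth. Whole-trajectory (non-
iterative) prediction is deliberately not implemented.
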