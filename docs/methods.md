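# Methods

## Problem and measurement chain

Late-gestation fetal MRI provides a 3D slab covering the whole uterus from
which fetal volume — and, via tissue density, fetal weight — can be measured.
`fetalvol` implements the measurement chain as five cooperating layers:
image model (grids, NIfTI I/O, resampling), segmentation (tri-planar 2D
U-net with vote fusion), quantification (volumes, density-based weight,
Dice), biometry (Hadlock formulas), flow (phase-contrast ROI integration and
weight indexing) and evaluation (Bland–Altman). A phantom generator supplies
inputs with closed-form ground truth so that every layer is verifiable
without patient data.

## Image model

Volumes are 3D scalar grids with per-axis spacing in mm and an origin;
label maps share the grid and use a fixed five-class alphabet
(0 background, 1 fetus, 2 placenta, 3 umbilical cord, 4 amniotic fluid).
The four intrauterine structures are the classification targets; the
explicit background class exists because softmax classification over a slab
that covers maternal tissue needs an "everything else" label. Only
axis-aligned (diagonal-affine) geometries are supported; NIfTI-1 is the
on-disk format, uint8 for labels. Acquired slabs are anisotropic (the
generator's default spacing, 1.8 × 1.4 × 2.5 mm, mirrors a typical
acquisition), while tri-planar slicing treats all axes equivalently, so
volumes are resampled to an isotropic grid before inference — trilinear for
intensities, nearest neighbour for labels so the label alphabet is
preserved. The conventional target is 1.5 mm (near the finest acquired
in-plane resolution, the default of `segment_volume`); the cohort-scale
tests and the demo pipeline run at 3.0 mm, the package's chosen desk-scale
operating point, which on the smooth phantom anatomy costs at most a
percent-level boundary error while cutting inference cost by roughly an
order of magnitude.

Resampling samples new voxel centres in the old index space (cell-centred
convention); physical extent is preserved to within one voxel per axis.

## Phantom generator

The phantom emulates a gravid uterus at reference scale as:

- **Uterus**: ellipsoid, semi-axes 140 × 112 × 118 mm, centred in the grid.
- **Fetus**: head ellipsoid (47 × 44 × 45 mm semi-axes) overlapping a trunk
  ellipsoid (105 × 62 × 56 mm) through a neck region, plus six cylindrical
  limb segments — per side a thigh whose length *is* the femur parameter
  (default 68 mm), a shank, and an arm — attached with their proximal ends
  embedded in the trunk so the voxelised fetus is one connected component.
- **Placenta**: ellipsoidal shell sector on the uterine wall: in
  normalised coordinates u = (p − c)/axes the set
  {0.80 ≤ ‖u‖ ≤ 1, ∠(u, n) ≤ 50°}; its volume is closed-form,
  abc·(2π/3)(1 − cos 50°)(1 − 0.8³) ≈ 676 ml at reference scale.
- **Umbilical cord**: constant-radius (8 mm) tube around a quadratic Bézier
  curve from mid-placenta to an anchor inside the trunk. The membership
  test is distance-to-centreline ≤ r, i.e. a Minkowski "sausage", whose
  volume is exactly πr²L + 4/3πr³ while the bend radius exceeds r.
- **Amniotic fluid**: the remaining uterus interior; **background**: the
  rest of the grid.

Voxel labels are assigned with priority fetus > placenta > cord > fluid >
background, so the cord's insertions belong to trunk and placental bed.

**Ground truth.** Per-solid volumes are closed form. The designed overlaps
among fetal solids (head∩trunk, limb∩trunk) are resolved by evaluating the
fetus *union* on a 0.5 mm quadrature grid over its bounding box — a
numerical step, but independent of the image-grid voxelisation and accurate
to ~0.1% (verified: voxel counts at default spacing agree with the truth to
0.03% for the fetus). The union at reference scale is cached and reused for
any `fetal_scale` via exact s³ scaling. Cord truth subtracts its quadrature
overlaps with fetus and placenta; fluid is the uterus volume minus the other
structures. Fetal weight is always 1.04 g/ml × fetal volume.

**Scaling.** `fetal_scale` similarity-scales the whole scene (uterus,
placenta, cord, fetus and the derived grid extent), emulating gestational
growth: geometry stays valid at any scale and all lengths/volumes transform
exactly. At reference scale the fetus is ≈ 2.10 l (≈ 2.18 kg); cohorts use
scales drawn uniformly from [0.97, 1.22], spanning roughly 2.1–4.0 kg to
mirror a late-gestation weight range. Generation checks containment by
sampling each solid's surface (cylinders are convex hulls of their end-cap
rims, so rim samples are the extreme points) and raises a geometry error if
the fetus leaves the uterus or touches the placenta sector.

**Signal model.** Class intensities are fixed constants (fluid 1.0,
fetus 0.55, cord 0.5, placenta 0.4, background 0.2) reproducing the
bright-fluid ordering of a bSSFP acquisition; a smooth multiplicative bias
field (three random-phase cosine plane waves, amplitude 0.2 by default) and
additive Gaussian noise (σ = 0.05 by default, i.e. 1σ between the two
closest classes) corrupt the image. Noise is Gaussian rather than Rician:
the pipeline's contracts do not depend on magnitude-MRI noise statistics.
Identical specs give bit-identical phantoms.

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: realistic fetal pose variation and articulation,
motion and banding artifacts, partial-volume fat/fluid interfaces, maternal
organ clutter, and human allometry. The last point matters for
interpretation: the phantom's trunk is a single ellipsoid, so its abdominal
circumference is large relative to its volume, and Hadlock estimates on
phantom biometry run well above density-based weight. Rank agreement
between the two weight estimators across fetal sizes is preserved (and
tested); absolute Hadlock-vs-MRI biases on phantoms are not meaningful.

**Flow phantom.** Each cardiac phase holds a parabolic (Poiseuille)
profile v(r) = v_peak(t)(1 − r²/R²) inside a vessel of radius R, zero
outside. Steady mode keeps v_peak = v_max; pulsatile mode uses
v_peak(t) = v_max(0.7 + 0.3 sin 2πt/RR), whose discrete cycle mean is
exactly 0.7·v_max. Ground truth is Q = mean(v_peak)·πR²/2 converted to
ml/min. Defaults (R = 5 mm, v_max = 20 cm/s, 14 phases, RR = 430 ms,
1.4 mm pixels, VENC = 150 cm/s) emulate a term umbilical vein at a typical
phase-contrast resolution and fetal heart rate, giving ≈ 471 ml/min.
Velocities above VENC are rejected at generation; aliasing is not modelled.

## Segmentation network and fusion

The slice classifier is a small U-net: `depth` (default 3) encoder levels of
two 3×3 conv + ReLU layers with 2×2 max-pooling, channels doubling from
`base_channels` (default 8), a two-conv bottleneck, nearest-upsample +
3×3 conv decoder with skip concatenation, and a 1×1 softmax head over the
five classes. It is written directly in numpy (im2col convolutions,
hand-derived gradients verified against finite differences in the tests,
Adam optimiser), float32, fully deterministic given a seed, and small
enough to train on one CPU in minutes. Slices are zero-padded symmetrically
to a multiple of 2^depth and un-padded after inference.

Training pools slices from all three axes of all training cases into one
shared model (a single network serving all three directions; per-axis models
were considered and rejected as tripling cost without benefit on phantoms).
Volumes are intensity-normalised to zero mean/unit variance per volume.
Slices with empty foreground are kept — background prevalence is
informative. The loss is class-weighted cross-entropy with
median-frequency weights clipped to [0.25, 8], without which the cord
(≈ 0.1% of voxels) would be ignored entirely. Each epoch draws
`slices_per_epoch` (default 240) slices without replacement; per-epoch
training and validation losses and final per-class validation Dice are
logged per fold. The k-fold harness shuffles ids deterministically and
splits validation sets as equally as possible (20 ids, k = 4 → 15/5).

Fusion is hard voting: each direction's argmax is one vote; majority (≥ 2)
wins; a three-way split goes to the tied class with the largest sum of the
three directions' probabilities, and any residual tie to the lowest class
index — a total order, verified exhaustively against a brute-force oracle
over all 5³ vote patterns. Where the three argmaxes agree the fused label
equals them regardless of probabilities. `segment_volume` chains resample →
predict ×3 → fuse → resample back to the native grid, then optionally keeps
only the largest connected fetal component (the fetus is one body; smaller
islands are relabelled background). Dice against a reference is always
computed on the reference's native grid so evaluation does not reward
resampling artifacts.

## Quantification, biometry, flow, agreement

- Volumes are voxel counts × voxel volume / 1000 (ml). Dice is
  2|A∩B|/(|A|+|B|), with the empty/empty case defined as 1 (perfect
  agreement about absence). Weight = 1.04 × volume (g/ml).
- Hadlock formulas 1–4 take cm and return grams via 10^L; inputs outside
  the usual physiological ranges (AC 15–45, FL 2–9, HC 15–40, BPD 4–12 cm)
  warn but compute, since the formulas degrade rather than break outside
  them. Within those ranges each formula is strictly increasing in each of
  its arguments (the negative AC·FL cross-terms never dominate there; this
  is asserted on a dense grid). Phantom biometry is closed form: BPD = the
  head's minor full axis; HC and AC = Ramanujan ellipse-perimeter
  approximations of the head's axial and the trunk's transverse
  cross-sections (exact for circles, < 10⁻⁴ relative error at these
  eccentricities); FL = the femur segment length.
- Flow = Σ_ROI v·ΔA per phase (1 cm/s·mm² = 0.01 ml/s), averaged over
  phases with equal weights (retrospective cine convention; the temporal
  integration scheme is otherwise unspecified in practice), × 60 for
  ml/min. Pixels are in or out of the ROI — no partial-pixel weighting,
  matching manual delineation practice. No background-phase or aliasing
  correction. Indexed flow divides by weight in kg.
- Bland–Altman: diff = a − b, bias = mean, SD with the n−1 denominator,
  limits of agreement bias ± 1.96·SD (large-sample form, no t-correction).
  Percent statistics use the per-pair mean as denominator — the standard
  ratio convention — and are reported as undefined if any per-pair mean is
  zero, while absolute statistics are always returned.

## Problem sizes and determinism

The cohort-scale demonstration (and its test) uses 28 phantoms — 20
train/validation with a fourfold assignment echoing a 15/5 split, 8 held
out — trains one fold's model for 8 epochs at 3.0 mm, and segments the test
set; with seed 1 it measures mean fetal Dice 0.978 and a maximum per-case
volume error of 2.9%, in about five minutes on one CPU. Unit tests use a
0.45-scale scene that generates in milliseconds. All randomness (cohort
scales, per-phantom noise, fold shuffling, weight init, slice sampling)
derives from explicit integer seeds; reruns are bit-identical on the same
platform.

## Known limitations

- Axis-aligned affines only; no DICOM, no oblique acquisitions.
- The phantom's geometric simplicity means segmentation performance there
  is an upper bound, not a predictor, for clinical images.
- Hadlock absolute calibration is not meaningful on phantom geometry (see
  above); only ordering comparisons are.
- The U-net is CPU-sized; no GPU path, no 3D context beyond tri-planar
  fusion.
- Flow ROIs must be supplied (or taken from the phantom's known lumen);
  there is no automatic vessel segmentation.
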