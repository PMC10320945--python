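# Methods

This package implements joint prediction of a 3D dose distribution and the
nine per-beam 2D fluence maps for nasopharyngeal-carcinoma-like IMRT plans,
together with everything needed to exercise the method end to end without
clinical data: a synthetic phantom generator with a reference-plan
optimizer, a simple forward dose engine, MLC fluence reconstruction, and
the dosimetric evaluation suite.

## Coordinate conventions and geometry

All volumes live on an isocenter-centered grid with 2.5 mm isotropic
voxels, indexed `[slice, row, col]` mapping to physical axes
(superior, posterior, left) in mm. Gantry angle 0° places the source
anteriorly; the angle increases toward patient-left. The nine treatment
beams sit at {0°, 40°, …, 320°} with a 1000 mm source–axis distance (SAD —
a machine constant the protocol leaves implicit; 1000 mm is the universal
C-arm linac value). Each beam's fluence plane is at the isocenter,
perpendicular to the central axis, 160×160 pixels at 2.5 mm pitch at full
scale, with the row axis parallel to the superior–inferior rotation axis.
Centering both grids at the isocenter makes fluence rows coincide 1:1 with
CT slices at the isocenter plane, which is what the patch logic relies on.

### The projection operator

For each beam, a sparse matrix `P` (n_voxels × n_beamlets) encodes the
divergent-beam geometry: the ray from the source through each voxel center
is intersected with the fluence plane and the voxel is assigned to the
nearest beamlet pixel (ties broken toward the lower pixel index) with
weight `(SAD/d)²`, where `d` is the source–voxel distance — the
inverse-square effect only, no attenuation or scatter. Nearest-neighbor
splatting is the default because it admits an exact brute-force oracle in
tests; voxels whose rays exit the plane are dropped and counted.
`f = Pᵀ·v` projects a feature volume to the plane; multiplication by `P`
is the exact adjoint, which is what makes the projection usable as a
network layer (gradients flow through the transpose).

Patch-restricted operators are obtained by slicing the full-volume matrix
to a 32-slice slab and a 32-row fluence window, deliberately *losing* the
entries that divergence carries outside the window. This reproduces the
truncated-projection edge effect: the outer rows of a patch fluence map
are under-covered by the patch volume, which is why the training loss
drops 3 rows per edge (32 → 26).

## Fluence reconstruction from control points

A field's fluence is the meterset-weighted sum of aperture transmission
masks over delivery segments. Each segment uses the leaf/jaw positions
interpolated at the midpoint of its two control points (one mask per
segment, rather than averaging two endpoint masks — a simpler rule with
identical behavior for static and near-linear segments). Pixel-center
sampling is the default; a ×N supersampling flag anti-aliases edges when
needed. Rounded leaf ends are modeled by widening each opening by half the
dosimetric leaf gap on both sides. The DLG (1.4 mm) and leaf transmission
(0.015) defaults are plausible Millennium-MLC-class values standing in for
unpublished commissioning data; both are required configuration, not
constants. Jaws are treated as opaque. Tongue-and-groove and head scatter
are out of scope.

## Synthetic phantoms and the reference plan

`generate_anatomy` builds an elliptical soft-tissue body with a bony
spine/mandibles and an air cavity, five targets (nested GTV/PTV-1/PTV-2
ellipsoids plus two mirrored nodal cylinders) and seventeen OARs at
anatomically plausible relative positions (cord/brainstem
posterior-central, parotids lateral and overlapping PTV-2, paired organs
mirrored). Positions and radii are jittered per seed; every case is
bit-reproducible from its seed. Prescriptions are sampled exactly from the
clinical sets: GTV/PTV-1/PTV-2 from {7000/6400/5800, 7000/6000/5400} cGy
and each nodal target from {6000, 6200, …, 7000} cGy; the PTV channel
carries, per voxel, the maximum prescription among covering targets.

The forward dose engine is intentionally simple:
`dose(i) = Σ_b f_b(j(i)) · (SAD/d_i)² · exp(−μ_eff · depth_b(i))`,
followed by an optional 3D Gaussian blur (σ = 3 mm) standing in for
penumbra and scatter. Radiological depth is the midpoint-rule integral of
relative electron density along the divergent ray (5 mm steps by default,
1 mm in the closed-form tests), with density from a two-segment HU ramp
(−1000 HU → 0, 0 HU → 1, +2000 HU → 2). μ_eff = 0.004 mm⁻¹ approximates a
6 MV broad-beam effective attenuation in water. Calibration is 1 cGy per
MU for an isocenter beamlet in vacuum. The engine is linear in fluence and
exposes its exact adjoint; this map (unsmoothed) also drives the
reference-plan optimizer, so the optimizer's gradient is exact. None of
this aims at convolution/superposition fidelity — the engine's job is to
create a learnable, physically plausible anatomy→dose/fluence mapping.

`optimize_reference_fluence` runs projected gradient descent (fixed step
from a power-iteration Lipschitz estimate, non-negativity projection each
step) on a weighted least-squares objective: unit weight toward the
prescription inside PTVs, weight 0.08 toward zero inside OARs, 0.02 inside
the remaining body. The warm start is the BEV PTV(+5 mm) footprint scaled
by an exact line search. With the default 50–60 iterations the GTV mean
dose lands within 10% of 7000 cGy on the desk-scale profiles (the final
Gaussian blur accounts for most of the shortfall).

## The shared-encoder network

One encoder, five resolution levels: level 1 is two 3×3×3 stride-1
convolutions; each deeper level is one stride-2 3×3×3 convolution and one
stride-1 3×3×3 convolution. Channels double per level (32 → 512 at full
scale) while the spatial size halves (32×224×224 → 2×14×14 at the
bottleneck). Every 3×3×3 convolution is followed by instance normalization
(with learned affine terms — the common default) and ReLU.

Two decoders with four levels each: trilinear upsampling to the skip's
spatial size, concatenation with the encoder skip, then two 3×3×3
convolutions per level — except the last level, which has one 3×3×3 and a
linear 1×1×1 output convolution. The dose decoder emits one channel. The
fluence decoder additionally concatenates the dose decoder's feature maps
at every resolution level (concatenation, matching the skip style, rather
than addition) and emits nine pre-projection channels — one per beam, the
package's central architectural reading of the projection head: channel
`b` is multiplied by its own beam's patch-restricted `P_bᵀ` to give the
9×32×160 fluence patch. The whole network is implemented directly on
numpy — blocked-GEMM 3D convolutions, instance norm, separable trilinear
interpolation, and the sparse projection head, each with a hand-written
exact backward pass (verified against float64 central differences to
better than 1e-6 relative) — so the package has no deep-learning framework
dependency. The decoders do not share upsampling parameters (upsampling
here is parameter-free interpolation).

## Training protocol

Inputs are 19 channels: the prescription-dose PTV mask (÷7000 cGy), the 17
OAR masks (alphabetical order), and CT (clipped to [−1024, 2000] HU,
÷2000) — stacked as 19×32×224×224 patches of 32 contiguous slices chosen
uniformly among windows containing at least one PTV slice. Dose targets
are normalized by 7000 cGy, fluence by 2000 MU.

Augmentation per sampled case: left-right flip with probability 0.6
(volumes mirrored; fluence beams remapped g ↔ (360−g) mod 360 with columns
reversed) and rotation about the superior–inferior axis by a uniform
multiple of 40° with probability 0.4 (nearest-neighbor for masks, linear
for CT/dose; fluence channels cyclically shifted — exact because the beams
are 40° apart). Both draws are independent, so a case is untouched with
probability 0.24.

The loss is the sum of two mean absolute errors on normalized scales: dose
over body voxels, and fluence over the BEV PTV(+5 mm) pixels restricted to
the middle 26 of 32 patch rows (3 trimmed per edge, the truncation
contract above). MAE is used throughout; the protocol's loss abbreviation
is read as mean absolute error, consistent with its evaluation metrics.
Adam at 3e-4, batch 2, reduce-on-plateau ×0.7 with patience 4 (relative
threshold 1e-4, no cooldown — framework-neutral defaults), 150 epochs of
400 iterations at full scale. Validation is augmentation-free and
restricted to PTV-containing slices (one deterministic, PTV-centered patch
per case, scored with the same masked dual loss); the checkpoint with the
best validation loss is kept. Augmentation draws are per-case, not
per-batch.

## Inference

Whole volumes are covered by 32-slice windows at stride 24 (8 overlap
slices); a final end-aligned window covers any remainder. Window outputs
are blended per slice with the logarithmic ramp `w(t) = ln(1+t)/ln(1+t_max)`
(t = distance to the nearer window edge, capped at the overlap width),
normalized to a partition of unity; slices covered by a single window are
copied verbatim. The specific logarithmic profile is this package's
declared interpretation of "logarithmic smoothing" and sits behind a
pluggable weight-profile interface (a linear ramp is also provided).
Blending happens on normalized values; denormalization (×7000 cGy,
×2000 MU) follows, with negative outputs clamped to zero and counted.
`renormalize_to_coverage` rescales a dose by bisection so its PTV-GTV
coverage at the prescription level matches a reference plan's (scale
bracket [0.5, 2], coverage tolerance 1e-4; an exactly matching dose
returns scale 1).

Because the clinical TPS steps (leaf-motion calculation and final dose
calculation) are proprietary, the "dose delivered by the predicted
fluence" arm of the three-way comparison is produced by the phantom
forward engine instead.

## Evaluation

Fluence, per beam within the BEV PTV(+5 mm) mask: MAE as % of the
ground-truth map maximum (per-beam maximum — the per-beam reading of the
normalization); SSIM (Gaussian 11×11 window, σ 1.5, K1=0.01, K2=0.03, data
range = reference maximum, mean over window-valid pixels); and global
gamma passing rates at 3%/3mm with 0% and 10% low-dose thresholds. The
gamma search scans a disc of radius 3×DTA on a 0.25-pixel grid with
bilinear interpolation; gamma is evaluated per-beam in 2D (no 3D dose
gamma is computed). Gamma is asymmetric in (reference, evaluated) by
construction. Dose: cumulative DVHs (10 cGy bins) and D95%/Dmean/Dmax per
structure in Gy; D95% uses the voxel-percentile convention (5th percentile
of voxel doses, lower interpolation). Cohort tables carry mean ± SD over
cases for all 5 PTVs and 17 OARs and two paired two-sided Wilcoxon
signed-rank tests per index (ground truth vs. predicted; ground truth vs.
fluence-generated; exact null for n ≤ 25, normal approximation with tie
correction above; all-zero differences reported as undefined).

## Scale profiles and problem sizes

Four presets bundle grid, model width and schedule:

| profile | grid | fluence | base width | schedule |
|---|---|---|---|---|
| micro | 16×48×48 | 9×32×32 | 8 | 4 ep × 25 it |
| tiny | 32×96×96 | 9×64×64 | 8 | 10 ep × 50 it |
| default | 64×224×224 | 9×160×160 | 32 | 20 ep × 100 it |
| paper | 64×224×224 | 9×160×160 | 32 | 150 ep × 400 it |

The micro and tiny profiles are the package's chosen desk-scale problem
sizes: they keep the full 9-beam geometry, the 2.5 mm resolution, the
five-level architecture and every protocol constant, while shrinking the
transverse field of view and the network width so that complete
train/predict/evaluate cycles run in minutes on one CPU core. The learning
smoke tests additionally use a reduced network width and elevated learning
rate, chosen once for those capacity checks. What passing desk-scale tests
demonstrates is that the pipeline's plumbing, geometry, gradients and
bookkeeping are correct and that the network can fit the synthetic
mapping; it says nothing about clinical-scale accuracy, which would
require the full dataset and schedule.

## What the phantom does not emulate

Real CT texture and heterogeneity beyond three tissue classes; deformable
or irregular anatomy; realistic sliding-window fluence modulation texture
(an optional smoothness penalty exists but is off by default); couch,
immobilization and artifacts; TPS dose-engine physics (AAA/Acuros-class
scatter and buildup). Findings on phantoms therefore validate mechanism,
not clinical performance.

## Numerical choices

Float32 network arithmetic with float64 accumulation where it matters
(losses, projections, metrics); instance-norm ε = 1e-5; He-normal
initialization seeded from the model config, with both decoders' output
1×1×1 convolutions zero-initialized — predictions then start at zero on
the normalized scale, which avoids a large early loss transient through
the projection head (each beamlet sums tens of voxel features) and makes
short desk-scale runs converge in hundreds rather than thousands of
steps; conv column buffers blocked
at ~150 MB so clinical-scale forward passes stay within a few GB of
memory; the degenerate case of a 1×1×1 bottleneck (instance norm has no
spatial statistics there) is avoided by requiring ≥ 32-pixel transverse
patches at five levels; empty masks make loss terms warn-and-skip and
metric functions raise; the Wilcoxon test requires ≥ 6 non-zero paired
differences.
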