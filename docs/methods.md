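# Methods

This note documents the modelling choices, parameter defaults and limitations
of the package, in the order data flows through it.

## Geometry and IO conventions

Volumes are 3-D scalar grids with strictly positive per-axis spacing in mm.
The internal canonical orientation is RAS (+x patient-right, +y anterior,
+z superior); NRRD files, whose ITK world frame is LPS, are flipped on the
first two axes at read time and restored at write time, so voxel-level code
never mixes conventions. Only axis-aligned orientations are supported — full
direction matrices and DICOM series ingestion are out of scope. Label maps
written to NRRD embed the label table (name, label value, colour) as
key/value metadata; NIfTI label maps get a JSON sidecar.

Resampling maps output voxel centres into the input grid; scalar volumes use
trilinear interpolation, label maps always nearest-neighbour. The output
shape per axis is `round(shape · spacing / target)` with round-half-away-from-
zero — stated explicitly because floating-point rounding conventions differ
between libraries and the shape contract is load-bearing for tests.
Intensity normalisation is plain min–max to [0, 1]; a constant volume maps to
all zeros (there is no signal to rescale, and the choice avoids a 0/0).
Percentile clipping before the rescale exists behind an explicit flag and is
off by default.

## The label scheme

32 FDI-coded teeth in quadrant order (11…18, 21…28, 31…38, 41…48 → classes
1…32), maxilla (33), mandible (34), left (35) and right (36) mandibular
canal; 0 is background. Left/right is patient-left/right in patient
coordinates — radiological display mirrors this, so the convention is stated
rather than assumed. The index order is serialized with every output; the
semantic merge (teeth/maxilla/mandible/canal) is a pure voxelwise
relabelling and therefore conserves foreground volume.

## The phantom

The phantom emulates the *structure* of a clinical dental CBCT study:
two elliptical dental arches carrying up to 32 teeth (crowns are truncated
ellipsoids; roots are tapered cones running from the crown centre into the
jaw, with root count depending on tooth type — incisor/canine 1, premolar 2,
molar 3 — so per-class shapes differ), maxillary and mandibular bone slabs
with a brighter cortical shell, and two tubular canals carved out of the
mandible along the arch curve. Intensities are drawn per structure
(background 0.05, trabecular bone 0.38, cortical 0.55, teeth 0.85, canal
lumen 0.12, additive Gaussian noise SD 0.03 — arbitrary units on a [0, 1]
scale, not calibrated Hounsfield values). Optional artifacts: radial
high-intensity spokes through a chosen crown (metal streak) and Gaussian
blur (motion). Geometry is parametric-analytic rather than atlas-based, so
every output is a pure, bit-reproducible function of the spec and seed.

Thin root cones can shed one- or two-voxel satellite fragments under coarse
voxelisation; a cleanup pass reverts satellites to the underlying backdrop so
each tooth is exactly one 6-connected component, which downstream instance
accounting relies on.

The default desk grid is 128×128×96 at 0.3 mm; the clinical 440×440×344 grid
is a configuration choice. What the phantom does **not** emulate: real
anatomical shape variation, tooth contact geometry, cone-beam physics,
calibrated attenuation, pathology. Tests that pass on phantoms therefore
demonstrate that the *pipeline* is correct and trainable, not that the
network reaches clinical accuracy — the latter requires real annotated data.

## Preprocessing and augmentation

Spatial augmentation is label-exact by default: axis flips and axis-aligned
90° rotations are voxel permutations applied identically to image and
labels, so the label value set is preserved exactly and tests stay
deterministic. Free-angle rotation (with nearest-neighbour labels) exists
behind a flag. Intensity augmentation is multiplicative scale 0.9–1.1 and
additive shift ±0.1 after normalisation — declared defaults, since no
canonical ranges exist. Patch sampling is a uniform random 64³ crop (inputs
smaller than the patch are padded symmetrically first); a foreground-biased
mode exists but is off by default.

## Network

* **Patch embedding**: non-overlapping 2×2×2 patches, linear projection to
  width 48 (stage widths 48/96/192/384 — the doubling mirrors the ×2 spatial
  halving). The attention head width is 8, so stage *s* runs 6·2^s heads.
* **Coordinate channels**: three normalised in-window coordinate channels
  are appended to the input (CoordConv-style, on by default). Instance
  labels are tied to *where* a structure sits (tooth 11 vs 21 differ by
  position, not texture), and a purely translation-equivariant network must
  learn position indirectly and slowly; explicit coordinates make the
  position→identity mapping directly learnable. Disable with
  `coord_channels=False`.
* **Window attention**: relative position bias per head, window 7³ by
  default (configurable); alternating blocks shift by half a window. Grids
  that do not divide the window are padded and the padding is masked out of
  attention, so padded voxels never contaminate real ones; shifting is
  disabled on axes where the grid does not exceed the window (it would
  degenerate to isolated tokens).
* **State-space block**: u = SiLU(conv₁ᵪ₁ᵪ₁(x) + conv₃ᵪ₃ᵪ₃(x)) (sum fusion),
  then a selective scan along each axis: Δ = softplus(Linear(u)) per channel,
  B, C = Linear(u) per position, diagonal A initialised to −(1…N) per
  channel, unidirectional forward recurrence, outputs of the three axes
  summed. The summed scan is normalised (instance norm) and added back
  through a sigmoid gate: with the gate closed the block reduces exactly to
  the convolutional path. The scan normalisation exists because the
  accumulated recurrence is an order of magnitude larger than the conv path
  and otherwise destabilises the deeper stages. State dimension defaults
  to 16.
* **Branch fusion**: channel concatenation + 1×1×1 projection ("stacking");
  additive fusion is available by configuration.
* **Decoder**: nearest ×2 upsampling + 3³ conv, skip concatenation, residual
  blocks (two 3³ convs with instance normalisation — the appropriate
  normalisation at batch size 1 — and an identity or 1³-projected shortcut).
  A full-resolution stem (3³ conv on the input) provides the last skip. The
  head is a 1×1×1 convolution over 37 classes; its weights are initialised
  ×0.1 so training starts from near-uniform class scores.
* **Head activation**: softmax over classes by default — the 37 labels are
  mutually exclusive and argmax decoding needs a normalised assignment. A
  per-channel sigmoid head is available (`head_activation="sigmoid"`) for
  fidelity with descriptions of the architecture that use one.

## Training protocol

70/20/10 random split (sizes `round(n·f)` with the remainder to training),
batch size 1, random 64³ patches, DiceCE loss (soft macro Dice over all
classes + voxel-mean cross-entropy, weighted 1:1 by default — the
conventional composite), AdamW, and a warm-up + cosine schedule: linear
0→lr over the warm-up (default 2 % of epochs), cosine lr→0 at the final
epoch. The clinical defaults are lr 1e-5 and 2500 epochs; the desk default
is 50 epochs. An "epoch" draws one random patch per training case
(configurable). Validation runs sliding-window inference on whole volumes so
validation curves reflect deployment behaviour; "accuracy" curves are
recorded as validation macro-Dice. Checkpoints carry weights, optimiser
moments, RNG state and curves, so a resumed run reproduces the uninterrupted
one bitwise. Ablation arms draw the identical data stream for a given seed,
which makes their curves comparable.

The numerical engine (`oralseg.nn`) is a self-contained NumPy reverse-mode
autodiff: float32 throughout, convolutions via im2col + GEMM (the input
gradient is one GEMM against the spatially flipped kernel), the state-space
recurrence as a fused primitive with a reverse-time adjoint scan. Gradients
are exact (verified against central differences); there is no
mixed-precision or multi-device support.

## Inference

Inputs whose spacing differs from the model's native spacing by more than 1 %
(relative) are resampled first and the labels mapped back to the caller's
grid afterwards. The volume is tiled into overlapping windows (default 64³,
overlap 0.5); per-window class scores are blended with a Gaussian bump
(σ = window/8, floored at a small positive value) or constant weights. The
accumulated weight field is strictly positive everywhere and the final
division makes the effective weights a partition of unity, borders included.
Decoding is per-voxel argmax with ties broken toward the lower class index,
so an all-equal tie yields background. Connected-component cleanup is
available but off by default — the published pipeline does not describe
post-processing, so fidelity comes first.

## Evaluation conventions

All per-class metrics are one-vs-rest voxel counts. Degenerate 0/0 ratios
score 1 (perfect agreement on absence); classes empty in both ground truth
and prediction are excluded from macro averages and routed to the
identification tally; classes empty in ground truth but predicted non-empty
are counted as false identifications and excluded from the macro by default
(a policy flag includes them as Dice 0 instead, covering the other
convention). Background is excluded from macro averages by default because
its dominance inflates accuracy-style metrics. "Predicted present" for the
tally means at least `min_voxels` predicted voxels (default 1). Per-case
reports are aggregated by unweighted means, with per-case CSV emitted so any
other aggregation can be recomputed.

ICC is ICC(2,1) — two-way random effects, absolute agreement, single
measures — computed from the ANOVA mean squares, which are reported
alongside the estimate for audit. The measurement fed to it is the per-label
volume (voxel count × voxel volume) per rater per case, the most common
choice when the original quantity is unstated; both choices are documented
in the output.

## The learnability benchmark

The package's core sanity property is that the full hybrid (reduced to
embedding width 24, 5³ windows, state dimension 8) memorises two phantoms —
32-voxel cubes at 1.2 mm spacing, chosen so one 32³ training patch covers
the entire 36-structure scene — within 400 optimisation steps, and that
sliding-window inference then reproduces the ground truth (macro Dice ≥ 0.8
on both measures). The benchmark uses the standard protocol with peak
lr 2e-3, 20-epoch warm-up and no weight decay (overfitting-appropriate
settings, declared once here). On one CPU the run takes about 10–12 minutes.
This demonstrates optimisation health (no dead branches, stable scales,
usable gradients through attention, scans and the decoder) — not clinical
performance.

## Known limitations

* Phantom realism is structural, not radiometric; no claim transfers to
  clinical CBCT without retraining on real data.
* The CPU engine is practical at desk scale (32³–64³ patches) only.
* Orientation handling covers axis-aligned RAS/LPS flips; oblique direction
  matrices are rejected territory.
* The state-space scan is unidirectional per axis; bidirectionality was left
  out to keep the recurrence primitive simple.
* Deciduous dentition and supernumerary teeth are outside the label scheme.
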