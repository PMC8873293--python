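# Methods

## Problem and scope

`couinaud3d` segments the liver of a portal-venous-phase (PVP) MR volume
into the eight Couinaud segments S1–S8 and evaluates such segmentations
the way radiologists do: quantitatively (overlap and surface-distance
metrics), qualitatively (how far each separating plane drifted, and
whether irregular inter-segment faults appear), and indirectly (whether
focal lesions would be assigned to the correct segment using the
automated map alone).

Real PVP MR datasets with per-segment ground truth are not publicly
available, so the package carries a synthetic phantom generator whose
ground truth comes from the same five-plane protocol the rest of the
package implements.  Everything below runs on a single CPU.

## Couinaud geometry

The classical protocol divides the liver with five surfaces:

* three vertical planes along the main stems of the middle, right and
  left hepatic veins (MHV, RHV, LHV).  The MHV plane runs from the
  midpoint of the inferior vena cava (IVC) through the MHV to the vertex
  of the gallbladder fossa and separates the left and right lobes.  The
  RHV plane splits the right lobe into anterior (S5/S8) and posterior
  (S6/S7) sections.  The LHV plane — continued inferiorly by the left
  longitudinal fissure — splits the left lobe into medial (S4) and
  lateral (S2/S3) sections;
* two horizontal (axial) planes through the right portal main stem and
  the sagittal left portal branch, separating superior from inferior
  segments (S8/S5, S7/S6, S2/S3);
* the caudate lobe (S1) is delimited by the curve from the
  venous-ligament fissure to the right wall of the IVC.

Implementation choices:

* Each vertical divider is realized as a single 3D total-least-squares
  plane fitted to its landmark polylines.  The MID plane fits the IVC
  midpoint, the MHV polyline and the gallbladder vertex jointly; the
  LHV/LLF plane fits LHV points at or above the left-portal level and
  fissure points below it.  The RHV plane is fitted to the vein polyline
  alone: the vein converges toward the IVC anyway, and leaving the IVC
  anchor out makes the divider respond rigidly (1:1, within a voxel) to
  a displacement of the vein, which the plane-shift rubric relies on.
* Plane normals follow a fixed orientation convention (first nonzero
  component positive).  Which side of a plane is "right lobe" or
  "lateral" is decided from the data: the sign of the covariance between
  signed distances and the appropriate world axis over the liver voxels.
  This keeps labeling invariant to the normal's arbitrary sign.
* Voxel membership is decided at voxel centers in physical mm; ties
  (signed distance exactly zero, or a voxel exactly at a portal level)
  go to the lower segment number.
* The caudate is carved out first; the plane rules label the remainder.
  Its separating surface is swept per axial slice from the
  venous-ligament curve to the IVC centerline offset by the IVC radius
  toward patient right; liver voxels posterior to that segment and
  within its lateral extent, inside the curve's axial span, form S1.
  A fissure placed outside the liver yields an empty S1 (a warning-level
  condition, not an error).

## Phantom generator

The generator emulates the features of PVP liver MR that matter to this
pipeline, not MR physics.  Study conditions (defaults):

* grid 96 × 96 × 64 voxels at 2 × 2 × 3 mm — the anisotropic
  thick-slice regime of breath-hold abdominal acquisitions (slice
  thickness of the emulated protocols is 3–4.4 mm);
* liver: ellipsoid with semi-axes 70 × 55 × 62 mm, jittered ±8% per
  case, radially modulated by a seeded combination of degree-1/2
  spherical harmonics with amplitude 0.15 × `shape_irregularity`
  (default 0.3).  The shape is star-convex about its center, hence
  always one connected component;
* landmarks: the IVC runs vertically near the posterior midline of the
  liver; the three hepatic-vein polylines radiate from its midpoint at
  azimuths of about 25°, 70° and 115° from patient-right (jitter ±4°),
  each with a gentle vertical bow, lying exactly in its dividing plane.
  The azimuths and IVC position were calibrated once so that every
  segment holds at least ~2% of the liver across seeds (left-lateral
  ≈ 9%, S4 ≈ 22%, right-lobe segments 11–17%, caudate ≈ 3%), matching
  anatomical proportions;
* intensities (arbitrary units): background 40, parenchyma 100, vessels
  160 (tubes of radius 3 mm around the vein polylines — vessels keep
  their segment label, they are not a separate class), hypo-lesions 60,
  hyper-lesions 150; multiplicative smooth bias field (amplitude 0.2)
  and additive Gaussian noise (σ = 8 by default);
* lesions: spheres with diameters drawn from 6–30 mm, centers uniform
  over liver voxels (optionally forced onto inter-segment boundaries),
  each recording the exact set of segment labels it overlaps.

What the phantoms do **not** model: cirrhotic deformation, vascular
anomalies, partial-volume fading, breathing motion, coil profiles,
k-space artifacts, non-liver organs.  Passing tests on phantoms
demonstrates that the pipeline's geometry, optimization and bookkeeping
are correct under idealized anatomy; it does not demonstrate clinical
accuracy on real MR.

## Segmentation network

A dual-branch 3D U-Net: a shared encoder–decoder whose output stage has
two sibling 1×1×1 convolution heads — a liver-boundary probability map
(auxiliary) and the 9-class voxelwise segment probabilities (final
output).  Blocks are (conv 3³ → batch-norm → ReLU) × 2; 2× max pooling
between encoder levels, nearest-neighbor upsampling plus skip
concatenation in the decoder.  Full-scale defaults are depth 4 / base 16
channels with 160³ patches; the CPU test scale is depth 2 / base 8 with
48³ patches.  Layers are implemented in numpy with hand-derived
backward passes, verified against central finite differences in the
test suite.

Design choices that matter:

* **Coordinate channels.**  In addition to the z-scored image, the input
  carries the three world coordinates normalized to [−1, 1].  Couinaud
  segments are defined by near-planar dividers at consistent absolute
  positions, and liver MR volumes are consistently oriented; a
  positional prior lets a shallow network resolve the partition.  The
  price is deliberate: predictions are not translation-equivariant.
  Disable with `ModelConfig.coord_channels=False`.
* **Input→head skip.**  The input channels are concatenated onto the
  final decoder features, so the linear heads see the coordinates
  directly — a hyperplane arrangement (the ideal-geometry solution) is
  then representable by the head alone, which accelerates recovery of
  the dividers by an order of magnitude at this scale.
* **Zero-initialized heads** start from uniform class probabilities,
  keeping early Dice gradients symmetric across classes.
* **Loss.**  Soft Dice averaged over the eight foreground classes
  (absent classes contribute through the ε = 1e-5 smoothing term) plus
  the boundary head's binary Dice, weighted 1:1.  Pure multiclass Dice
  has a known failure mode from random initialization: once the softmax
  suppresses a class, its Dice gradient vanishes (there is no log term)
  and small segments never recover — we observed S1/S2 pinned at zero
  Dice over hundreds of SGD steps.  `TrainConfig.ce_weight` (default
  1.0) therefore adds a voxelwise cross-entropy companion; setting it to
  0 recovers the pure-Dice reading.
* **Optimization.**  SGD with momentum 0.9 under a step-decay schedule
  `lr(epoch) = lr0 · 0.1^(epoch // every)`; the full-scale defaults are
  lr0 = 1e-3, decay every 50 epochs, batch 8, 150 epochs.  The scaled
  desk protocol uses lr0 = 0.5 decayed late in the run (epoch 16 of
  20 for the parameter-recovery experiment), batch 1 (batch
  statistics come from ~110k voxels of a single 48³ patch, so
  batch-norm remains well fed, and a single CPU gets four times as many
  updates per second as with batch 4), two random crops per case per
  epoch, ≤ 20 epochs.
* **Inference** resamples to the target spacing, z-scores, tiles with
  50% overlapping windows, averages the fused probabilities (patches
  sorted by offset so fusion is order-independent), takes the argmax,
  and maps labels back to the native grid by nearest voxel center.

## Evaluation stack

* **DSC** (%): `2|X∩Y| / (|X|+|Y|) × 100`; two empty regions agree
  perfectly (100, logged).
* **MSD** (mm): symmetric mean of nearest-neighbor distances between
  the two surface point sets, normalized by `N_X + N_Y`.
* **HD** (mm): symmetric Hausdorff distance (exact maximum, not a
  percentile).  Distances are Euclidean in physical mm; surfaces are
  voxels with a 6-connected background neighbor, with the grid edge
  counting as background.  KD-trees provide the nearest-neighbor
  queries but are contracted — and tested to 1e-9 — against the
  brute-force all-pairs computation.
* **RV**: volume ratio `V_X / V_Y` in mm³.
* Averages are unweighted means over the eight segments; labels absent
  from the reference are excluded and logged.

## Clinical rubric

Plane shifts are measured per divider from the inter-segment boundary
voxels of the relevant label pair (e.g. {5,8} vs {6,7} for the RHV
plane): vertical dividers by fitting planes to both maps' boundary
voxels and evaluating their separation at the liver centroid's
projection (mm); horizontal dividers as the difference of median
boundary slice indices (slices).  Grades: vertical ≤ 5 mm slight,
≥ 10 mm severe, between moderate; horizontal ≤ 2 slices slight, ≥ 5
severe, between moderate (boundary values bind to slight and severe
respectively; a numerically zero shift is recorded as "none" and not
counted).  An unmeasurable boundary grades severe.

Inter-segment faults are mislabeled 26-connected components of at least
1 cm³ whose centroid lies at least 10 mm from every reference
inter-segment boundary — errors a shifted plane cannot explain.

Overall class: **poor** on any severe shift or fault; **good** with no
moderate shift and at most two slight shifts, or exactly one moderate
shift and no slight shift (read strictly: one moderate plus any slight
is moderate); otherwise **moderate**.

Indirect evaluation filters lesions to those larger than 5 mm and at
most the five largest per liver (ties to lower id), then assigns each
lesion every predicted label covering ≥ 10% of its voxels plus the
modal label.  The 10% floor ignores one-voxel spills while still
reproducing the boundary-push failure mode in which a large lesion
pressing on a divider is read as cross-segmental.  A lesion wholly
outside the predicted liver counts as a localization failure.
Inter-rater agreement uses the linearly weighted kappa
`κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij`, `w_ij = |i−j|/(k−1)`, checked
against an independent implementation in the tests.

## Problem sizes and numerical conventions

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen
as this package's study conditions: 96 × 96 × 64 phantoms for labeler
and training checks (48 × 48 × 32 for unit fixtures), 20 training / 5
held-out phantoms at depth 2 / base 8 / 48³ patches for the parameter-
recovery experiment (the acceptance script uses 12 / 3 with 11 epochs),
≤ 15³ random masks against the quadratic surface-distance oracle, and
100-phantom batches for partition checks.  All randomness flows from
explicit integer seeds through `numpy.random.Generator`; reruns with
the same seed are bit-identical on a fixed platform and thread count.

## Known limitations

* The plane-based labeler realizes each divider as one global plane
  (the radiologists' per-slice curves are only approximated); the
  caudate's "natural curve" is one reading of an under-specified rule.
* Phantom realism is geometric, not radiometric; generalization to real
  MR is untested here and requires clinical data.
* The positional prior (coordinate channels) assumes consistently
  oriented, roughly centered livers; volumes with unusual framing would
  need the prior disabled and a deeper network.
* The exact-maximum Hausdorff distance is sensitive to single-voxel
  outliers; percentile variants are intentionally out of scope.  At
  desk scale the network's argmax occasionally labels isolated stray
  voxels far from a segment, so held-out mean HD is dominated by those
  outliers even when DSC is high — inference applies no morphological
  post-processing by design.
* Lesion localization from model predictions is much weaker than from
  ground-truth labels at this scale: lesions near a divider pick up
  neighboring labels under the 10% occupancy rule whenever the
  predicted plane is a few mm off — the same boundary-push confusion
  observed clinically, amplified by the small network.
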