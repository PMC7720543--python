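# Methods

`bcadepth` segments bladder-cancer tissue from adherent bladder-wall tissue
on 3D T2-weighted MR volumes by voxel-wise classification, and measures how
deep the tumor has invaded the wall from a streamline-based wall-thickness
map. This note records the model, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open.

## Problem setting and assumptions

Bladder tumors grow from the lumen side into the wall. On T2W MRI the tumor
and the wall have similar intensity and a weak boundary, so a plain
threshold cannot separate them; intensity *context* and texture can. The
pipeline assumes:

* the inner and outer wall surfaces are available as binary shell masks
  (from an external surface segmentation, or from phantom ground truth) —
  surface segmentation itself is out of scope;
* a *candidate region* — a mixed tumor+wall region around the lesion — is
  either supplied or detected from a wall-thickness anomaly;
* classification operates only inside the candidate region, trained on
  tumor and wall voxel samples of approximately equal size.

## Voxel features (1159 per voxel)

Each voxel gets 3 location features (its x, y, z indices) plus 68 features
on each of 17 images: the original volume and 16 wavelet images, obtained
from a 2-level undecimated (stationary) 3D wavelet transform keeping all 8
subbands per level, so every image stays voxel-aligned with the original.
The wavelet family is configurable (default Haar); only the image count is
fixed by the design. Per image:

* **20 intensity features** — intensities of the voxel and its 6 face
  neighbours; means of the in-plane 3×3 patches centred at those 7 voxels;
  the 6 centre-minus-neighbour differences. Neighbourhoods that leave the
  image are handled by edge replication so every candidate voxel stays
  featurizable.
* **48 texture features** — responses of the Leung–Malik filter bank: 18
  first-derivative and 18 second-derivative oriented Gaussian kernels (6
  orientations × 3 scales, envelope elongation 3), 8 Laplacian-of-Gaussian
  and 4 Gaussian kernels. Filters are 2D and applied on the axial slice by
  convolution with edge replication; derivative/LoG kernels are zero-mean
  and L1-normalized, Gaussians sum to one. Defaults: support 49×49,
  oriented scales σ₀·{1, √2, 2} with σ₀ = 1 voxel; the LoG/Gaussian family
  extends the progression with a fourth scale 2√2·σ₀ (LoG also at 3× those
  scales), which is the canonical LM construction.

Total: 3 + (20 + 48) × 17 = 1159, in a fixed, named column order so
matrices from different volumes are train/predict compatible. Features are
computed on the native grid; no standardization happens at extraction time
— the z-scoring is fit on training rows inside the classifier, where its
effect on weight-based feature elimination is explicit and testable.

## Classification and segmentation

A linear-kernel SVM (libsvm backend, C = 1.0 by default) on z-scored
columns. Feature selection is SVM-RFE: refit, eliminate the `step` columns
with the smallest |w| (ties: highest column index), repeat; the subset
size is the smallest N maximizing mean stratified fivefold CV accuracy
over a size grid. `step = 1` reproduces the classical procedure; the
pipeline default (50) is a speed knob that changes only granularity of the
ranking, not the selection logic. The linear kernel is required: |w| is
only meaningful as an elimination criterion for a linear decision function.

Probabilities are a Platt sigmoid p = 1/(1+exp(A·f+B)) fitted on training
decision values with smoothed targets. The **hard boundary** thresholds p
at 0.5, keeps the largest 26-connected component and fills enclosed holes;
the **soft boundary** is the set of candidate voxels with 0.1 ≤ p ≤ 0.9
(endpoints inclusive — the measure-zero-safe reading), interpreted as the
mixed tumor/wall interface zone. Segmentation quality is scored by the
Dice coefficient DSC = 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks.

## Wall thickness by Laplace streamlines

On a 1 mm isotropic grid (anisotropic inputs are resampled: linear for
intensities, nearest-neighbour for masks), Laplace's equation is solved
over the wall interior with Dirichlet boundaries — inner shell at 0, outer
shell at 1 — by red–black Gauss–Seidel (tol 1e-6 on the max per-sweep
update, max 10,000 iterations). The discrete maximum principle keeps the
potential inside (0, 1); the background is classified as lumen-side (0) or
exterior-side (1) so the gradient is defined in a band around the wall.

From every inner-shell voxel a streamline follows the normalized trilinear
gradient by second-order Runge–Kutta (step 0.25 mm) until it crosses into
the outer shell; the crossing is refined by bisection on the nearest-voxel
membership. Thickness is the accumulated arc length minus half a voxel:
the seed sits half a voxel inside the inner shell, so the correction makes
a slab of N one-mm layers measure N mm (verified against the slab and the
concentric-sphere closed forms; the spherical 10→13 mm shell measures a
mean 2.92 mm). Streamlines that stall, leave the domain, or exceed the
step budget are flagged invalid and excluded (counted in the report).

**Candidate detection stand-in.** The abnormality detector that defines
the candidate region in the source protocol is specified only in prior
work, so this package ships a thickness-anomaly stand-in: seeds with
thickness above median + k·MAD (k = 3 by default, a free parameter) are
abnormal, and the candidate is the set of wall voxels traversed by their
streamlines, morphologically closed. A user-supplied candidate mask
bypasses detection; the phantom pipeline defaults to the ground-truth
candidate for exactly that reason.

## Invasion depth

The segmented tumor is excised from the wall domain; the cavity joins the
lumen, and the inner surface is recomputed on the residual wall (tiny wall
fragments orphaned inside the cavity by an imperfect segmentation are
folded into the cavity; a disconnected piece larger than 5% of the wall
raises a topology error). On the re-solved thickness map:

* T_mean — mean thickness over seeds away from the candidate footprint
  (excluding the whole candidate, not just the tumor, avoids lesion bias);
* T_min — minimum thickness over seeds in the cancer footprint, defined as
  inner-shell voxels bordering excised tissue, dilated by one voxel. A
  config switch widens the domain to the full candidate footprint, and an
  optional percentile floor replaces the absolute minimum; the defaults
  stay with the cancer footprint and the absolute minimum.
* T_ID = T_mean − T_min. Negative values (thickened residual wall) are
  reported as-is and flagged.

At 1 mm resolution the error contributed by a single voxel is 1 mm, which
is the tolerance used for all depth-recovery checks.

## The phantom: what it emulates, what it does not

Real study data (20 patients, expert delineations) are not publicly
available, so the pipeline is exercised on synthetic phantoms: an
ellipsoidal lumen (default semi-axes 17/15/14 mm on a 64³ 1 mm grid)
surrounded by a wall of uniform 3 mm thickness built from the Euclidean
distance to the lumen; a spherical-cap tumor (radius 8 mm) centred on the
inner surface, protruding 6 mm into the lumen and excavating the wall to a
configurable invasion depth (the excavation front follows an iso-distance
surface, so the planted depth is exact up to voxelization). Tissue
intensities mimic T2W contrast — bright urine (210), hypointense wall
(100), intermediate tumor (118), exterior 45, all ± an SD of ~6–12 — with
per-tissue Gaussian random fields (white noise smoothed at the tissue's
correlation length: 0.5 voxels for wall, 1.8 for tumor) so texture carries
class signal beyond the mean shift. A 1-voxel partial-volume blur at
interfaces creates the weak boundary the soft boundary is meant to
capture. These contrast values are free parameters of the phantom, not
claims about real tissue statistics.

Not modelled: MR physics (coil inhomogeneity, Rician noise), irregular or
multiple tumors, patient-to-patient intensity variation, motion. Passing
phantom tests therefore demonstrates the machinery — feature
informativeness, selection, calibration, geometry — not clinical
performance on real T2W data.

## End-to-end batch and problem sizes

The default batch trains on 4 phantoms (300 voxels/class each, sampled
with a 1 mm margin from the tumor interface; wall samples near the
candidate region) and validates on 10 phantoms with invasion depths
cycling through {0.5, 1.0, 1.5, 2.0} mm, all on 64³ grids — sizes chosen
so the full batch runs in minutes on one CPU while keeping several
thousand candidate voxels per case. Training spans the same depth range as
validation (both sets are draws from one phantom population, as the
source protocol randomized patients between sets). Each case reports DSC
against the true tumor mask and the invasion depth computed twice — from
the ground-truth mask and from the pipeline segmentation — whose
difference isolates the segmentation's effect on the depth estimate. All
randomness fans out from one seed through a seed sequence; a config+seed
pair reproduces the report byte-identically.

Typical results at the defaults (seed 1): per-case DSC 0.88–0.95, mean
0.92; mean |ΔT_ID| ≈ 0.7 mm, dominated by the shallow-invasion cases where
a one-voxel over-segmentation moves T_min by a full voxel.

## Numerical choices and degenerate inputs

* Resampling preserves physical extent to within one voxel per axis
  (output shape = round(nᵢsᵢ/target)); constant volumes are preserved
  exactly; masks are re-binarized after nearest-neighbour interpolation.
* Wavelet axes are edge-padded to a multiple of 2^levels and cropped back.
* RFE ties on |w| eliminate the highest column index (determinism); CV
  grid ties pick the smallest subset size.
* Empty hard segmentation is a warning plus an empty mask, not an error;
  empty candidate detection likewise.
* An empty cancer footprint or an empty normal-wall region in the depth
  stage is an error (the statistic is undefined there).
* The Laplace solver raises on non-convergence and on wall components
  with no path to both surfaces.

## Known limitations

* 2D (axial) texture filters; no 3D LM variant.
* The thickness-anomaly candidate detector is a stand-in with a free
  parameter k; it is not the bent-rate detector of the source protocol.
* Streamline pairing is traced inner→outer only.
* Voxel-pooled CV folds; no per-case (grouped) folding in the default
  path, though the selection API accepts any precomputed folds seed.
* The phantom's tumor is a smooth spherical cap; real lesions are
  irregular, and DSC on real data would be lower.
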