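# Methods

`tmjmorph` quantifies three-dimensional change of temporomandibular-joint
(TMJ) structures between two imaging timepoints — typically before and
6–8 weeks after mandibular surgery — and compares two surgical arms
(mandibulotomy, which splits the mandible for tumor access, vs. transoral
resection) on imaging and clinical outcomes.

## Measurement model

Each joint is observed twice with two co-acquired modalities: a
high-resolution bone-contrast volume (CBCT-like; condyle bright) and a
soft-tissue volume (MRI-like; articular disc is the darkest structure,
cortical bone faintly dark). The pipeline is

1. **Fusion.** The soft-tissue volume is rigidly registered onto the bone
   volume by maximizing mutual information (MI), giving one mm-space frame
   per joint.
2. **Segmentation.** The condyle is thresholded from the bone volume
   (Otsu's criterion when the threshold is `auto`), restricted to the
   largest 26-connected component, optionally closed morphologically;
   add/erase masks reproduce expert manual correction (erase wins on
   overlap). The disc is ingested as a mask, or dark-thresholded from the
   soft volume.
3. **Reconstruction.** Binary masks become triangle meshes by marching
   cubes at level 0.5 after a Gaussian pre-smoothing (σ = 1 voxel); the
   smoothing removes the staircase artifact that inflates surface areas of
   raw binary isosurfaces by ~9%. If smoothing would erase a structure only
   a few voxels across, the raw mask is meshed instead. Sharp rims (e.g. a
   phantom half-ellipsoid base) are rounded slightly; enclosed volume stays
   within a few percent of the voxel count.
4. **Morphometry.** Between timepoints:
   * DSI = 2·|M₁∩M₂| / (|M₁|+|M₂|) on voxel masks — 1 means no
     displacement, 0 full displacement;
   * surface distances by nearest point-to-triangle correspondence, pooled
     over both directions: the RMSD summarizes the distance field, the
     Hausdorff maximum is its extreme;
   * MxD: the maximum magnitude of the per-vertex signed distance from the
     disc surface to the condyle surface (sign positive outside the
     condyle), with the signed channel exported as a PLY color map.
5. **Cohort statistics.** Two-sample Hotelling T² (pooled covariance, exact
   F conversion) with per-outcome mean differences, pooled-t standard
   errors and 95% CIs; Spearman rank correlations with the conventional
   strength bands (|r| ≤ 0.3 negligible, ≤ 0.5 low, ≤ 0.7 moderate,
   ≤ 0.9 high, else very high; band edges close the published guide's gaps
   upward); and a two-arm sample-size helper.

### Interpreting RMSD vs. displacement

For a rigidly translated convex body, nearest-point distances on surface
patches whose normals are orthogonal to the translation are ≈ 0, so the
pooled RMSD is a fixed fraction of the displacement (≈ d/√3 for a sphere,
≈ 0.55·d for the condyle phantom), while the Hausdorff maximum equals the
displacement. RMSD is therefore reported as a field summary; displacement
magnitude recovery is read from the Hausdorff maximum. Conversely a thin
spur on an otherwise identical body leaves DSI near 1 with a huge Hausdorff
maximum: the two metrics answer different questions (displacement vs. shape
change) and are always reported together.

## Registration details

* Objective: MI in nats over a 32×32 joint histogram with **linear (Parzen)
  soft binning** over fixed intensity windows. Hard binning leaves the
  objective too jagged for sub-degree accuracy at desk-scale sample counts.
* Sampling: fixed-image voxel centers jittered off-grid by a fixed seeded
  uniform offset (±half voxel). On-grid sampling systematically favors
  grid-aligned (zero-rotation) poses — the known MI interpolation artifact,
  observed directly on phantoms — because samples then hit moving-image
  voxels exactly and sharpen the histogram.
* Optimizer: deterministic staged search. A 3×3×3 translation multi-start
  grid (±4 mm) at zero rotation seeds a translation-only Powell pass, then
  full 6-parameter Powell passes restarted at finer sampling and lighter
  smoothing (σ = 1 then σ/2 voxels; restarts matter because Powell's
  conjugate directions degrade). Rotation center is the fixed-image center.
* Convergence: MI change < 1e-6 nats or 200 iterations per stage;
  non-convergence flags the result rather than raising.
* Accuracy on phantoms (≤ 6 mm, ≤ 10° true misalignment, noise sd 0 and
  0.05): residuals ≲ 0.05 mm and ≲ 0.3°, comfortably within the half-voxel
  / 1° contract. Public `mutual_information()` uses plain histogram MI at
  voxel centers so that MI(X, X) equals the histogram entropy exactly.

## Synthetic data

Real joint images are not redistributable, so validation runs on analytic
phantoms with closed-form oracles:

* **Condyle**: upper half-ellipsoid, default semi-axes 9 × 6 × 7 mm
  (medio-lateral × antero-posterior × vertical, realistic for an adult
  condylar head); volume (2/3)πabc.
* **Disc**: biconcave lens seated above the condyle with a 0.8 mm joint
  space; outer radius 6 mm, center thickness 1.2 mm, edge thickness 3 mm,
  parabolic thickness profile; volume πR²(t_c+t_e)/2.
* **Intensities**: bone volume — condyle 1.0 on 0.35 background; soft
  volume — disc 0.05, condyle 0.18 (cortical bone is dark on MRI; with the
  condyle strictly invisible in the soft volume the two modalities would
  share no anatomy and MI would be locally flat at the optimum), background
  0.35. Gaussian noise sd 0.05 by default; 0.5 mm isotropic grid (0.25 mm
  where an oracle demands finer sampling). All generators are deterministic
  under their seed.
* Equal balls at separation d give the closed-form overlap Dice
  (4r+d)(2r−d)²/(16r³), used as the displacement-measurement oracle.
* **Cohort simulator**: per-joint imaging outcomes and per-patient clinical
  outcomes drawn from group-specific truncated normals (DSI in [0,1],
  distances ≥ 0, JFLS integer 0–50, mouth opening > 0) whose default
  moments are the empirical moments of the built-in fixture table.

What a green phantom test does **not** establish: anatomical realism
(no fossa/eminence, no condylar remodeling textures, no MRI bias fields or
CBCT beam-hardening), registration robustness beyond ±6 mm/10°, and
segmentation behavior on pathological intensity distributions.

## The built-in cohort fixture

The per-joint and per-patient outcome table of the source cohort
(9 mandibulotomy patients / 18 joints; 7 transoral patients / 14 joints) is
embedded as structured data. Two transcription conventions are recorded in
the fixture metadata: the published clinical group averages are
floor-truncated at one decimal (the per-patient integers admit no rounding
parse), and the one incompletely printed transoral row is resolved by
requiring the printed column averages (flagged in metadata). Missing cells
are handled by pairwise deletion everywhere — never imputation.

## Unit of analysis

Imaging outcomes and imaging–clinical correlations are computed per joint
(n = 32), with each patient's clinical values replicated to both joints;
clinical-only summaries are per patient. Caveat: replication makes the two
joints of a patient perfectly correlated on clinical outcomes, which
inflates joint-level test sizes (measured type-I ≈ 0.14 at nominal 0.05 in
simulation); the type-I property is therefore demonstrated on independent
per-joint outcomes, and clinical comparisons are run at patient level.

## Power helper

Sample size uses the classical normal-approximation table formula
N = ((z₁₋α/₂ + z_power)/f)² for a two-group comparison at Cohen's f,
rounded up and split across arms: α = 0.05, power = 0.8, f = 0.8 gives
7 per arm. The exact noncentral-F power at that n (0.785) is also reported;
the approximation is what the standard printed tables contain. Dropout
inflates recruitment by 1/(1−dropout), rounded up.

## Numerical choices

* Distances: point-to-triangle (region-based closest point), exact KD-tree
  pruning that provably returns the brute-force minimum; ties between
  equidistant triangles may pick either.
* Resampling: masks nearest-neighbor, intensities trilinear; mask volume
  changes ≤ 2% under any rigid resampling. Fill outside a source volume is
  configurable; modality misalignment uses edge replication because
  constant fill would fabricate dark borders that a dark-polarity disc
  threshold then segments.
* Crop boxes select voxels whose centers fall in the half-open box, so a
  25 × 27 × 25 mm box at 0.25 mm spacing is exactly 100 × 108 × 100 voxels.
* Segmentation order: threshold → drop components below the minimum size →
  keep largest 26-connected component → closing; each stage raises a named
  error if it empties the mask.
* Spearman uses average ranks for ties; correlations with fewer than three
  complete pairs raise.

## Known limitations

* Rigid registration only; no deformable model, no multi-resolution pyramid
  beyond two smoothing levels, single-threaded.
* The disc dark-threshold path assumes the disc is the darkest connected
  structure in the (registered) soft volume.
* Hotelling T² assumes equal group covariances (pooled estimator).
* DICOM ingestion is out of scope; volumes are NIfTI-1.
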