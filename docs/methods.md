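# Methods

## Problem and approach

After a Latarjet procedure — transfer of the coracoid process onto the
anterior glenoid rim, fixed with two 4.5 mm screws — the bone graft
progressively resorbs. Quantifying that loss in 3D normally requires an
early post-operative CT as the volume baseline, an extra irradiation.
This package implements a patient-specific alternative that needs only the
scans that already exist: the pre-operative CT and the long-term follow-up
CT.

The measurement chain:

1. **Segmentation.** Bone is thresholded two-sidedly
   (`bone_threshold <= HU < metal_threshold`); the screws scan far above
   cortical bone and are segmented separately at `metal_threshold`. A
   one-voxel dilation of the metal mask is subtracted from the bone mask to
   suppress the partial-volume blooming halo around metal. Closed surfaces
   are extracted with marching cubes at the 0.5 iso-level.
2. **Registration.** The pre-operative scapula surface is rigidly
   registered onto the follow-up surface (trimmed ICP, details below).
   This puts the intact pre-operative anatomy into the follow-up frame.
3. **Virtual osteotomy.** The registered pre-operative scapula is cut at
   the marked osteotomy plane; the piece distal to the plane is the
   *modeled timepoint-zero graft* — the bone block exactly as harvested.
   Its volume is the baseline V0.
4. **Graft placement.** The modeled graft is positioned on the glenoid by
   aligning its inferior third to the inferior third of the actual
   follow-up graft. The inferior region is used because it is consistently
   spared by resorption, so it remains a reliable anchor even when the
   superior graft is gone.
5. **Isolation.** Follow-up bone voxels inside the registered
   (osteotomized) pre-operative scapula are native bone and are removed;
   what remains adjacent to the anterior glenoid is the remodelled graft.
   Fitted screw heads are removed so metal never contributes volume.
6. **Volumetry and grading.** Resorption = 100·(V0 − Vf)/V0 (positive =
   loss; clinical tables print losses negative and reports carry both
   conventions). A geometric surrogate of the Zhu grade is derived from
   screw head/shaft exposure; the patient grade is the maximum over the
   two screws.

## Registration details

Initialization pairs centroids and principal axes; the per-axis sign
ambiguity (four right-handed candidates) is resolved by scoring each
candidate's mean nearest-vertex distance on a deterministic subsample.
Degenerate inertia spectra fall back to centroid-only alignment with a
warning.

The ICP uses nearest-point-on-triangle correspondences from a subsample of
moving vertices (default 1500, fixed seed). Two non-obvious choices proved
necessary:

- **Annealed trimming.** The two scapulae genuinely differ (harvested
  coracoid, added graft), so the worst correspondences must be discarded —
  but a *fixed* 20% trim creates local minima: at moderate misalignment the
  high-curvature points that pin down rotation are exactly the
  worst-distance ones. Trimming is therefore annealed (20% → 10% →
  outlier-only) with convergence required at each level. Callers can also
  exclude a marked vertex region outright; the pipeline automatically
  excludes the coracoid side of the osteotomy plane (plus a 3 mm margin) in
  a second refinement pass, which improves rotation recovery roughly
  five-fold.
- **Point-to-plane steps.** Pure point-to-point updates converge extremely
  slowly in tangential "sliding" modes of a blade-like bone (hundreds of
  iterations from a 15° initialization). After a 5-iteration point-to-point
  warm-up, updates use the linearized point-to-plane solve, clipped to a
  trust region (≤ 0.03 rad, ≤ 1.5 mm per step) because the linearization is
  only valid for small increments. Convergence requires both rms stagnation
  (change < `tolerance`, default 1e-4 mm) and a negligible pose increment;
  with surface noise the rms plateaus at the noise floor while the pose can
  still be sliding, so rms stagnation alone is not trusted.

Both steps are deterministic; registration results are bit-reproducible
for a fixed seed.

## Geometry kernel

Plane cuts, voxelization, point containment and closest-point queries are
implemented in `graftmorph._mesh` on top of the trimesh container:

- **Capped plane cut.** Crossing triangles are split on shared,
  exactly-cached edge-intersection points; the cut loops are chained by
  edge identity and capped with a triangle fan from the loop centroid. For
  a *planar* cap the divergence-theorem volume depends only on the boundary
  loop, not its triangulation, so the fan is exact even for non-convex
  sections, and because both halves share identical intersection points and
  mirror-image caps, `V(graft) + V(remainder) = V(mesh)` holds to floating
  precision (observed ≤ 4e-16 relative over 50 random solids).
- **Voxelization** rasterizes closed meshes slice by slice: the plane
  section loops are rasterized with even-odd polygon tests at voxel
  centres.
- **Volumetry** uses the signed-tetrahedron (divergence theorem) sum and
  demands watertightness; non-watertight input is a hard error reporting
  the boundary-edge count, never silently repaired.

## Screw handling

Each metal component is fitted with a cylinder-plus-head model: PCA gives
the axis; a per-bin radius profile along the axis gives the shaft radius
(median of the tip-side bins, plus a half-voxel digitization correction)
and locates the head (contiguous end bins with radius > 1.3× shaft).

Volumes at the two timepoints must be commensurable. The modeled
timepoint-zero graft is cut from the screwless pre-operative coracoid, so
the screw-occupied interior counts as graft there; the follow-up bone mask,
by contrast, has metal-shaped tunnels excluded by thresholding. The
isolation stage therefore *fills* the fitted shaft cylinder (plus the same
one-voxel blooming margin segmentation subtracts) — but only over axial
bins where graft bone still surrounds the shaft in most angular sectors.
Where the surrounding ring has resorbed away, the shaft is genuinely
exposed and stays hollow; filling it would both inflate the volume and hide
the exposure from the grader. Fitted screw heads (plus margin) are always
removed. Without the fill rule the two volumes would differ by ~15% by
construction — a segmentation artifact, not resorption.

## Geometric Zhu surrogate

The original grading is a radiologist's visual call on axial CT; the
surrogate makes it reproducible: sample points on the fitted head surface
and on the shaft surface over the span that traversed the graft at
timepoint zero (the pipeline derives that span from the modeled graft's
extent along the screw axis; the deeper shaft is buried in native glenoid,
which the graft mesh does not include). Head buried (≥ 95% of head samples
inside the graft) → grade 0; head exposed but shaft covered (≥ 95%) →
grade 1; shaft partially exposed with graft still within 2 mm of it →
grade 2; no graft, or none within 2 mm → grade 3. The sampled shaft span is
inset 1.5 mm at both ends because exactly at the entry/exit faces the
sample ring straddles the curved graft surface even with zero resorption.
All thresholds (95%, 95%, 2 mm) are explicit configuration values echoed
into the report. Near grade transitions the surrogate can disagree with
the voxel-level bookkeeping by one grade — the coverage statistic is
evaluated on a reconstructed surface with half-voxel jitter — which is the
same boundary ambiguity human raters face.

## Statistics

- **Kendall tau-b** (ordinal grade vs continuous resorption) comes from
  the tie-corrected statistic with the asymptotic tie-adjusted p-value; the
  95% CI is a bias-corrected percentile bootstrap (10 000 resamples, fixed
  seed). Degenerate resamples (a constant column) are dropped.
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure — is computed from the two-way ANOVA mean squares, with
  McGraw–Wong Satterthwaite F bounds for the 95% CI and the
  MS_rows/MS_error F test for the p-value. Identical rater columns return
  ICC 1; zero between-subject variance returns 0 with a warning.
- **Per-grade summaries** report n, volume means/SDs and the mean
  per-patient resorption percentage per grade plus an n-weighted pooled
  row. Note the two percentage conventions: the pooled volume-ratio
  100·(V0̄ − V̄f)/V0̄ and the weighted mean of per-patient percentages differ
  (31.4% vs ~31% on the reference cohort summary); summaries label both.

## Phantoms: what they emulate, and what they do not

No patient imaging is distributable, so all validation runs on schematic
digital phantoms with exact ground truth. The scapula is a thin blade
ellipsoid plus a glenoid boss, a spine-like ridge and an inferior-angle
knob (the last two exist purely to give registration the rotational
anchors a real scapula has); the coracoid is a capsule of radius 7 mm and
length 26 mm, giving a graft of ≈ 2 700 mm³ — the scale of real grafts.
The follow-up scene performs the operation with known parameters: known
osteotomy plane, known graft pose on the anterior rim, two screws
(4.5 mm shaft, 8 mm head proud of the graft surface), a known resorbed
fraction applied as a deterministic surface-first erosion weighted along a
chosen anatomical gradient (removal sets are nested in the fraction, so
truth volume is strictly monotone), a known rigid inter-scan transform,
and Gaussian noise (σ 20 HU). Default spacing is 0.75 mm isotropic,
matching the slice thickness of the scanner protocol the technique was
validated on; intensities are background 0 / bone 700 / metal 3000 HU.

Ground truth is integer voxel bookkeeping recorded before noise. Screw
heads sit proud of the graft at timepoint zero, so phantom cohorts contain
no grade-0 cases — consistent with the validation cohort, where every
patient showed resorption; grade-0 behaviour of the surrogate is tested on
synthetic enclosing grafts instead.

What the phantoms deliberately do not model: partial-volume intensity
ramps, beam hardening and streak artifacts, trabecular texture, cartilage,
anatomical shape variation, and graft–glenoid bony fusion. Passing the
phantom suite therefore demonstrates the geometric and statistical
machinery recovers known truth under noise, repositioning and metal
occlusion — not that segmentation of real, artifact-laden CT is solved
(the study design assumes a human segmenter for that step).

The stratified phantom cohort draws per-grade resorption fractions from
normal distributions centred on the published per-grade losses
(12.3% / 31.5% / 58.3% for grades I/II/III, n = 8/18/5). The parametric
cohort simulator draws per-patient volume pairs from the published
per-grade means/SDs; rater noise defaults (150 mm³ between raters, 50 mm³
between sessions of the same rater, about 5% and 2% of a typical graft)
represent manual-segmentation variability with inter-rater differences
larger than intra-rater ones. With those inputs the simulated reliability
(ICC ≈ 0.93 inter, ≈ 0.99 intra) and the grade–resorption correlation
(tau ≈ 0.5–0.7, positive in > 99% of seeds) fall in the range the
technique reports on real patients — emergent behaviour, not a fit.

## Problem sizes and numerical defaults

Tests and the acceptance script run phantoms at the study's native 0.75 mm
spacing (≈ 1–2 M voxels per volume, surfaces of ≈ 50 k faces); registration
recovery uses 20 seeded transforms, the end-to-end sweep 5–7 resorption
fractions, the statistical oracles 100 tau datasets, 50 ICC matrices and
500 simulated cohorts. Regional mapping voxelizes grafts at 0.5 mm. Key
defaults: bone threshold 226 HU (a common cortical preset — the original
workflow is manual in a commercial tool and names no number), metal
threshold 2000 HU, marching iso-level 0.5 with 0.3-voxel Gaussian
pre-smoothing (heavier smoothing measurably biases enclosed volume),
ICP trim 20% annealed, graft–glenoid adjacency 2 mm (one voxel diagonal at
study resolution), inferior region = lowest third along the
superior–inferior axis.

## Known limitations

- The osteotomy plane and (optionally) a glenoid landmark are user-marked
  inputs, as in the original workflow; their placement error propagates
  directly into V0.
- The surrogate grade is sensitive to the fitted screw geometry; severely
  bloomed or touching screws can merge into one metal component (a warning
  reports component counts).
- Apparent graft *growth* (negative resorption) is measured and reported
  but not specially modelled; remodelling that fuses graft and glenoid
  seamlessly can make the native/graft boundary ambiguous at the
  one-voxel level.
- Volumes are reported from both the isolated surface mesh and raw voxel
  counts; they differ by O(one surface voxel layer), and the difference is
  a useful internal consistency check.
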