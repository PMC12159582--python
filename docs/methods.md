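# Methods

## Problem and pipeline

Revision total hip arthroplasty planning needs the three-dimensional
geometry of acetabular bone defects: how much bone is missing, where, and
how deep. Given a watertight surface mesh of a pathological hemipelvis
(millimetre units, as produced by CT segmentation), `acetrec` reconstructs
the missing-bone solid in five stages:

1. **Native anatomy estimate.** A PCA statistical shape model (SSM) of
   defect-free hemipelvises is fitted to the pathological surface, giving a
   subject-specific estimate of the bone before any loss.
2. **Acetabular frame.** The concave articular cup of the native estimate
   is detected, a sphere is fitted (hip joint centre, acetabular radius),
   19 rim points define the acetabular plane, and the polar axis is the
   plane normal pointing out of the cup. A global superior-direction hint
   (default +y) pins the in-plane superior/anterior axes.
3. **Ray-cast defect extraction.** From the hip joint centre, a Fibonacci
   lattice of ray directions (default spacing 1°, ≈41 000 rays) is cast
   into both the native estimate and the pathological surface. Along each
   ray the solids' inside-intervals follow from crossing parity (at most 4
   retained intersections per surface, range capped at 2.5× the acetabular
   radius); defect intervals are (inside native) AND NOT (inside
   pathological). Recorded points (endpoints, midpoints, 1 mm
   densification) are clustered by single linkage; clusters under 200
   points are discarded; survivors are surfaced with a 3D alpha shape.
4. **Boolean refinement.** (defect − pathological) ∩ native, realized as
   voxel Booleans (crossing-parity rasterization at 0.7 mm + marching
   cubes); disconnected droplets under 0.5 cm³ are removed.
5. **Regional metrics.** Absolute defect volume (ADV, cm³), relative defect
   volume (RDV, % of regional native bone, native = SSM estimate ∪ defect)
   and mean defect depth (DD, mm) are reported for superior / posterior /
   anterior angular sectors (extents 2.2×, 1.9×, 1.9× the acetabular
   radius), a medial-wall cylinder (radius 0.86×, extending 2.5× medially
   from the joint centre), and overall ("total" = union of the regions).

Validation compares the reconstruction against ground truth with
volumetric Dice (shared 1 mm grid), volume MAE/MARE, and symmetric
Hausdorff distance (surface samples at ≥10 points/mm² against the exact
opposing surface, converging from below).

## Synthetic anatomy

No CT data ships with the package; every stage is exercised on parametric
hemipelvis phantoms: a rectangular bone block (default half-extents
80 × 80 × 60 mm) with a hemispherical articular cup (radius 25 mm) opening
through its top face. This preserves every feature the pipeline consumes —
concave cup, sharp rim, surrounding cortical surface — while keeping
analytic ground truth. The surface is built by explicit structured
parametrization (radial top-face grid, spherical cap, side/bottom grids),
so all members of a population share identical topology and the SSM
correspondence is exact by construction; the rim circle is an actual
vertex ring.

The training population (57 members by default) varies six parameters:
three block half-extents (SD 4, 4, 3 mm), cup radius (Normal(25, 2) mm),
and two in-plane cup offsets (SD 2 mm). Extents and radius share a common
size factor (correlation 0.9) with independent residuals: real acetabular
size scales with pelvis size, and that correlation is what lets a shape
model predict the articular surface from the surrounding bone after the
excision step hides it.

Pathological subjects are new draws from the same distribution, posed with
a random rotation ≤10° and ±20 mm translation (CT-derived surfaces arrive
in standardized orientation; the fit is initialized accordingly). Defects
are carved as unions of spheres/ellipsoids anchored to the subject's cup
frame; the pathological surface is produced the way segmentation pipelines
produce it — signed-distance sampling on a 1.25 mm grid re-surfaced with
marching cubes. Three presets span the clinically reported range: a
contained cavitary sphere (~10 cm³ at r = 25 mm), a deeper medial
ellipsoid (~30 cm³), and a two-lobed medial + superior-wall loss
(~80 cm³); preset factors scale with the subject's cup radius, so truth
volumes vary a few tens of percent across subjects. Ground truth is
analytic membership (native ∧ primitive-union) evaluated at 0.5 mm voxel
centres — below the 0.7 mm median slice thickness of typical clinical CT.

The standard study suite is 12 cases (3 presets × 4 subjects).

What the phantom does **not** emulate: real cortical/trabecular texture,
anatomical landmarks (teardrop, ischium), osteophytes, segmentation noise
and metal artifact, or non-spherical dysplastic cups. Passing the suite
shows the geometry pipeline is correct and self-consistent at clinical
defect scales; it does not certify accuracy on patient CT.

## Shape model and fitting

Generalized Procrustes alignment (similarity transforms) followed by PCA
on stacked vertex coordinates; mode weights are expressed in standard
deviations and clamped to ±3 SD during fitting. The first 20 modes are
used for native-anatomy reconstruction.

Fitting alternates correspondence and a linear weight solve until the
maximum weight change falls below 1e-4 SD (≤50 iterations):

* **Corresponded targets** (same template topology) pair vertex *i* with
  vertex *i*; weights and the similarity transform are solved jointly by
  Gauss–Newton. (Alternating the two estimates stalls at a fixed point
  where a spurious transform is compensated by spurious weights.)
* **Arbitrary targets** use closest-point-on-surface pairing (KD-tree over
  face centroids, exact triangle projection) with robustness gates — pairs
  facing away from the template normal or beyond max(3× median, 8 mm) are
  dropped — and a hybrid point-to-plane + 0.5-weighted point-to-point
  solve with a relative ridge (1e-4). Point-to-plane alone lets the
  box-like phantom slide along its own faces and collapse into large
  cavities; point-to-point alone biases the weights. Iteration stops once
  the gated mean residual falls below 0.1 mm: beyond the surface
  discretization scale, weakly observed modes only drift in their null
  space.

`estimate_native` is a two-pass excision scheme with refinements:

1. A similarity-only registration of the model mean aligns the outer
   anatomy, with the template's own acetabular neighbourhood (2.5× cup
   radius) excluded a priori — defects are confined to that ball by
   construction, so this registration never sees pathological bone.
2. The cup is additionally sought directly on the pathological surface:
   concave-curvature votes are clustered (a defected pelvis can contain
   two concave spherical regions — the acetabulum and the cavity), and a
   cluster consistent with the registration (within 0.7× radius, radius
   ratio 0.7–1.4) is accepted as the measured joint sphere.
3. The masked 20-mode fit runs with the excision ball removed from the
   correspondence set. When the joint sphere was measured, the template's
   articular patch is instead given explicit targets — its radial
   projection onto that sphere (the native articular surface *is* the
   joint sphere, whether bone remains there or not).
4. Up to four refinement rounds re-centre the excision ball on the current
   estimate's frame and re-include ball vertices already lying on the
   pathological surface (conformity tolerance 2.5→1.2 mm, widened
   adaptively when a measured sphere indicates a larger offset).

## Numerical choices

* **Voxel engine.** Solids are rasterized by crossing parity along scan
  columns; grids carry irrational sub-voxel jitter so columns avoid mesh
  vertices/edges; isolated odd-parity columns (grazing artifacts) are
  repaired, larger counts raise a watertightness error. Pipeline Booleans
  rasterize along x at 0.7 mm; the test-only voxel oracle rasterizes along
  z at 0.5 mm on a differently jittered grid, or uses analytic membership
  for synthetic solids. Marching cubes re-surfaces masks (watertight by
  construction); volumes are divergence-theorem volumes of the result.
* **Ray casting.** Single-origin batched Möller–Trumbore; triangles are
  culled by their angular footprint around the origin via a KD-tree over
  ray directions; grazing duplicate hits merge within 1e-6 mm. A ray whose
  intersections were truncated by the 4-hit cap is excluded from
  classification (parity beyond the last retained hit is unknowable).
* **Noise filters.** Defect intervals thinner than 2 mm along the ray, or
  whose midpoint lies within 1 mm of the pathological surface, are
  dropped. Both thresholds are calibrated to the native estimate's
  sub-millimetre uncertainty (reported SSM reconstruction errors are
  ~0.8 mm RMSE); the clearance filter exists because rays nearly tangent
  to the articular surface stretch a sub-millimetre radial error into
  centimetre-long chords (2·sqrt(2·r·δ) ≈ 11 mm at δ = 1 mm).
* **Clustering / alpha shape.** Linkage radius = 2× the inter-ray arc
  length at the excision range (≈2.2 mm at 1°); alpha = 3× linkage.
  Degenerate (near-planar) clusters raise an error.
* **Defect depth.** Per ray: furthest defect-interval endpoint minus first
  native intersection, floored at zero; rays with no pathological hits use
  the native exit (full-thickness loss). Regional DD averages rays with
  positive depth only — averaging zeros over non-defect rays would make DD
  an artifact of ray density — and a ray is assigned to every region
  containing one of its interval midpoints.
* **Sector rule.** Strict dominance (superior component > |anterior|
  etc.): points on the polar axis belong to no angular sector; the
  medial-wall cylinder covers them. Regions may overlap; they are not a
  partition.
* **Dice convention.** Two empty masks score 1.0 (null defects agree).

## Known limitations

* The native estimate's articular accuracy depends on either an intact cup
  portion (measured sphere) or population size-correlation; anatomies far
  outside the training distribution degrade both.
* Screw holes or any bone void inside the excision ball count toward
  defect volume; no attempt is made to exclude them.
* Defects extending beyond 2.5× the acetabular radius from the joint
  centre are truncated at that range by design.
* The regional "total" is restricted to the union of the four regions;
  bone loss in the inferior gap between the anterior and posterior sectors
  is not attributed to any region.
* Left hemipelvises are not mirrored; inputs are assumed right-sided in a
  standardized orientation.
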