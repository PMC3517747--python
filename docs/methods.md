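# Methods

`kneekin` measures 3D tibiofemoral and patellofemoral kinematics from
segmented knee geometry and validates the whole chain on a parametric knee
phantom with exactly known ground truth. This note records the models,
conventions, numerical choices, and what the synthetic validation does and
does not demonstrate.

## Coordinate conventions

All coordinates are world millimetres. The package-wide anatomical sign
convention (for a right knee) is **lateral +x, anterior +y, proximal +z**;
orientation hints (rough world-space guesses for proximal / lateral /
anterior, available from scan orientation) fix only axis *signs*, never
axis directions. Signed outputs follow: anterior translation positive,
femoral internal rotation positive, patellar tilt open-to-medial positive,
patellar shift lateral positive. Whether the original protocol reported
anterior- or posterior-positive AP values is not documented anywhere we
could rely on; anterior-positive is adopted and applied consistently.

Voxel grids use the voxel-centre convention: voxel `(i, j, k)` has its
centre at `origin + spacing * (i, j, k)`, 0-based.

## Tibial frame

The tibia-based reference frame has its origin at the **area-centroid** of
the tibial-plateau articular surface (area-weighted mean of triangle
centroids). Axes come from the area-weighted principal axes of the plateau
triangulation: `z_t` is the smallest-variance direction (plateau normal,
sign proximal), `x_t` the largest in-plane spread (medio-lateral, sign
lateral), `y_t = z_t x x_t` (anterior). How "spatial orientation" becomes
axes is a design choice; principal axes are landmark-free and
deterministic. For near-circular plateaus (in-plane variance ratio below
1.05) the in-plane spread cannot orient `x_t`, so it falls back to the
lateral hint projected into the plateau plane — this tie-break exists so
that one subject's frames never flip between acquisitions, which is what
cross-condition comparability rests on (each acquisition builds its own
frame; no cross-pose registration is performed).

## Epicondylar axis

The posterior femoral condyles approximate a single cylinder over the
flexion arc. Both posterior condylar articular surfaces jointly (the
trochlea excluded) feed a least-squares cylinder fit minimising
`sum((distance_to_axis - r)^2)` over five parameters: axis direction as two
spherical angles, a 2D anchor in the plane orthogonal to the direction, and
the radius. The solver is damped least squares (Levenberg–Marquardt,
`xtol = ftol = 1e-15`) initialised from the largest principal direction of
the point cloud (the condylar patches extend furthest along the axis); a
user-supplied guess overrides the initialisation. The axis sign is
canonicalised medial→lateral from the tibial `x_t` (or hints). Inputs with
fewer than 6 points, or coplanar/collinear clouds, are rejected. On exact
cylinder data the fit recovers radius and axis to 1e-6 for arbitrary
orientation; the reported residual is the RMS of the minimised distances
and is rigid-motion invariant.

Reference points: the medial and lateral condylar surface centroids are
projected orthogonally onto the fitted axis; the femoral centre is their
midpoint. Axis-projection points (rather than epicondylar surface points)
are used because the axis is what is carried into the tibial frame.

## Tibiofemoral kinematics

Reference points are expressed in each pose's own tibial frame
(`local = A (p - origin)`, `A` rows `x_t, y_t, z_t`). AP position is the
local y-coordinate. Epicondylar rotation is the signed angle in the tibial
transverse plane between the projected medial→lateral vector and `x_t`,
wrapped to (−180°, 180°], internal rotation positive; a near-vertical axis
(transverse projection below 1e-6 of the vector norm) is an error. Deltas
between two poses of one subject are plain differences (b − a), rotation
wrapped; they are antisymmetric by construction and zero on identical
poses. Varus/valgus and compression are out of scope — only AP translation
and axial rotation are reported.

## Patellar frame and patellofemoral parameters

The patella-based coordinate system (PBCS) puts its origin at the patellar
centre **C**, computed as the centroid of the enclosed volume of the closed
patellar mesh (divergence-theorem, robust to non-uniform meshing; open
meshes are rejected). `Py` (longitudinal, superior) and `Px`
(medio-lateral, lateral) are the first and second principal directions of
the vertices; `Pz = Py x Px` points anterior. Note that with these senses
the ordered triple `(Px, Py, Pz)` is left-handed — the senses, not the
triple's handedness, carry the anatomy, and every signed output documents
its own convention. The inferior patellar pole IPP is the vertex
minimising `(v − C)·Py`.

The four parameters:

* **Patellar height** — Euclidean distance from IPP to the line through the
  tibial origin along `x_t` (mm, ≥ 0).
* **Patellofemoral angle** — angle between `Py` and the femoral long axis
  (first principal direction of the shaft mesh, proximal; the shaft must be
  elongated, extent ratio ≥ 2), in [0°, 180°], increasing with flexion.
* **Patellar tilt** — signed angle, in the PBCS transverse plane, between
  the trochlear facet line `Pmin1→Pmin2` and `Px`; medial opening positive.
* **Patellar shift** — `(C − Pmax) · x_t`, lateral positive, with `Pmax`
  the sulcus-floor reference point.

### Trochlear landmark operationalisation

The textual definitions of `Pmin1`/`Pmin2`/`Pmax` ("shortest/largest
distance of the sulcus to the y–z plane") do not uniquely identify points
on a continuous surface: any vertex adjacent to the x = 0 contour minimises
|x|, making the landmark line direction mesh noise. The package therefore
operationalises the landmarks as the 3D analogue of the classic 2D axial
indices, a choice documented prominently here:

1. the trochlear surface is intersected with the PBCS transverse plane
   through C (the axial slice through the patellar centre);
2. the resulting section curve is analysed in its *own* in-plane axes —
   medio-lateral = major principal direction of the section, anterior =
   toward the patella — because scoring in the raw PBCS axes degrades when
   the patella is strongly tilted (the patellar "anterior" rotates away
   from the groove's);
3. `Pmax` is the posterior-most interior section point, with the outer 20%
   of the medio-lateral span excluded per side so the cartilage-label rim
   cannot masquerade as the floor;
4. `Pmin1`/`Pmin2` are the anterior-most section points up to 25 mm medial
   / lateral of the floor, each refined by a local parabola fit (±6 mm)
   whose vertex replaces the raw argmax — on rough re-extracted surfaces
   the fit suppresses vertex noise, and under imposed tilt the linear term
   shifts both facet argmaxima equally so the fitted line preserves the
   tilt angle.

On phantom meshes this operationalisation is exact (see below) and is
monotone in imposed tilt and shift. A `snap_to_vertices` option moves
landmarks to the nearest mesh vertices when vertex landmarks are required.

## Geometry I/O

NIfTI label volumes (nibabel) are the canonical voxel input; meshes (PLY /
STL via trimesh, ASCII PLY written by default) may bypass voxels entirely.
Label interpolation is always per-label on 0/1 indicator fields — never on
raw integer codes — and upsampled voxels take the label of the largest
interpolated indicator if it reaches 0.5, else background. Tri-linear
upsampling by integer factor f maps n voxels to `f(n−1)+1`, preserving
endpoint voxel centres; the interpolation target resolution is exposed as
configuration (default 0.5 mm isotropic). Surface extraction runs marching
cubes at level 0.5 on the indicator after smoothing it with a 1-voxel
Gaussian: the raw binary field yields a staircase isosurface whose area
overestimates a sphere's by ~9%, while the smoothed field's area error is
~2% and its RMS surface distance at 1 mm voxels is ~0.13 mm (the smoothing
radius is a parameter; 0 disables it, and structures thinner than the
kernel fall back to the unsmoothed field).

## The knee phantom

Because no imaging data accompany the study design, validation runs on
parametric knees in the tibial reference pose (plateau in z = 0, centred):

* tibia: elliptical slab (35 × 25 mm semi-axes) with the plateau disk at
  z = 0;
* condyles: posterior arc patches (arc 150°–260°, radius 20 mm) of a
  cylinder about the epicondylar axis 25 mm above the plateau, patch
  centroids at ±28.6 mm;
* femoral shaft: 120 mm cylinder along the flexed femoral axis
  (flexion swings the proximal end posterior, as in sitting);
* trochlea: a W-profile groove, `depth · |sin(pi x / 2 x_p)|` with
  depth 6 mm and facet peaks at ±16 mm, extruded 36 mm along the shaft,
  placed 14 mm posterior of the patellar centre (clear of the patella so
  rasterised labels never overlap);
* patella: a triaxial ellipsoid lens (ML 15 / AP 8 / SI 20 mm semi-axes)
  built from a uv-sphere so its poles are exact mesh vertices.

Posing splits into two compartments. The **condylar complex** realises the
tibiofemoral dials: imposed medial and lateral AP positions place the
epicondylar axis, and the axial rotation follows as
`asin((lateral − medial)/(2 d))` with d = 28.6 mm — rotation is *derived*,
not an independent dial, because the three quantities are geometrically
coupled. The **trochlear compartment** (shaft, trochlea, patella) is posed
by the flexion angle and the four patellofemoral dials, constructed so each
drawn value is realised exactly (IPP placed at the drawn height from the
tibial ML axis; patellar long axis at the drawn angle to the shaft; tilt as
a rotation about `Py`; the patellar centre the drawn shift lateral of the
groove floor). The trochlear compartment deliberately does **not** inherit
the condylar axial rotation: a rigid femur would couple that rotation into
the groove direction and perturb the landmark-based ground truth by up to
~2 mm. This is a phantom simplification — real femora are rigid — and it
means the phantom validates the measurement operators, not the internal
consistency of a rigid femur across compartments.

Height and patellofemoral angle are unsigned; a negative drawn value
realises geometry whose true measurement is the absolute value, and the
ground truth stores that folded value (material only in low-flexion cells
whose calibration mean sits within ~1 SD of zero).

Rasterisation evaluates each structure's analytic membership on the grid:
solids filled, articular surfaces as 2 mm shells centred on the true
surface so re-extraction is unbiased.

### Motion models

Healthy defaults (the source figures are qualitative; magnitudes are
package choices, configurable): medial/lateral AP of (−1, +4) mm at 0°,
(−2, −2) at 30°, (−5, −10) at 90° — rollback with lateral > medial
posterior translation and 10.0° external rotation over 0→90°, identical
with and without flexor activity. PCL-deficient defaults match healthy at
0° and 30°, then show paradoxical medial anterior translation of +6 mm from
30° to 90° (lateral near-constant), +8 mm under flexor activity, with
correspondingly reduced external rotation. The four patellofemoral dials
default to the published per-condition means, and cohorts draw them from
normals with the published means and SDs (healthy n = 20, PCL-deficient
n = 12); condylar AP dials get a 2 mm between-subject SD (a package choice;
no tibiofemoral spread is published). Draws are independent per condition
with an optional shared per-subject intercept (default 0). Sampling is
fully seeded and bit-reproducible.

## Statistics

Summaries are per-cell sample mean and SD (n−1). Comparisons are two-sided
Student t-tests: paired on within-subject differences (df = n−1), unpaired
between groups with pooled variance by default (matching the era's
statistics-package default) and Welch behind a flag. Zero-variance paired
differences return an explicit degenerate flag (all-zero differences are
reported as t = 0, p = 1). No multiple-testing correction is applied, and
the mixed-model factor analysis of the source design is deliberately not
reimplemented.

A known negative result, retained in the acceptance suite: the published
group-significance pattern (tilt and shift significant at 90° only) is not
reproducible from the published summary statistics. With means 4.7 ± 5.0
(n = 20) vs 6.7 ± 5.4 (n = 12), the pooled t for shift at 90° has power
≈ 0.18 (tilt ≈ 0.65); 0 of 50 seeded replicate cohort pairs reproduce the
full pattern. The calibration was not adjusted to manufacture agreement.

## Verification summary and limitations

What the tests establish: exact (≤ 1e-6) recovery of every imposed
quantity on mesh input across all 12 default conditions and 16 seeded
stress cohorts (1,920 scenes); recovery within 1.5 mm / 2.0° through 1 mm
voxelisation and re-extraction; exact cylinder recovery at arbitrary
orientation; rigid-motion equivariance of frames and invariance of all
parameters; closed-loop reproduction of the published 90° calibration
means within two standard errors for both cohorts; paired-t type-I error
5% ± 0.6% over 10,000 null replicates.

What they do not show: performance on real segmentations (no statistical
shape variation, no segmentation error, no MR intensity artefacts — the
voxelisation path is the only realistic degradation modelled); the
phantom's two-compartment femur means cross-compartment rigidity is not
exercised; landmark behaviour on strongly asymmetric trochleas (the
phantom groove is symmetric; facet asymmetry would offset the tilt zero
point by a constant per knee, cancelling in condition differences but not
in absolute values).

Problem sizes in the default test run — single scenes per condition,
cohorts of 20/12 at one condition for closed-loop checks, one 1-mm voxel
scene, 50 draw-level cohort replicates for the significance pattern,
10,000 vectorised null replicates for the t calibration — were chosen so
the suite exercises every path at full fidelity on a single CPU.
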