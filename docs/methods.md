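# Methods

This note documents the models, conventions and numerical choices behind
`psitunnel`, and what the synthetic-data pipeline does and does not
demonstrate about real surgical data.

## Anatomical frame

Tunnel angles are clinical quantities read off CT planes, so they need a
per-knee coordinate system. The frame is built from five landmarks:

- **SI axis**: normalized shaft direction (proximal − distal diaphyseal
  point). Defines the axial plane (everything orthogonal to SI).
- **ML axis**: the inter-epicondylar direction Gram–Schmidt-orthogonalized
  against SI, oriented from the entry epicondyle *into* the bone. Together
  with SI it spans the coronal plane.
- **AP axis**: completes the triad, signed so the most anterior trochlear
  point has a positive AP coordinate.
- **Origin**: the entry-side epicondyle.

Building the frame per entry side (ML medially for lateral tunnels,
laterally for medial tunnels) means one angle convention — "anterior
positive, proximal positive" — serves all four ligaments. A consequence is
that the triad's chirality alternates with side (the lateral frame is the
sagittal mirror of the medial one); no computation depends on handedness,
because all angle math is done in frame coordinates. Construction fails
explicitly when the epicondylar axis is within 1e-6 (relative) of parallel
to the shaft axis. Frame construction is exactly equivariant under rigid
motions and yields mirror-consistent angles for left knees; both properties
are tested.

The landmark-based construction is a deliberately transparent surrogate for
published CT coordinate-system protocols; it reproduces the axial/coronal
planes as used clinically and is swappable behind the `LandmarkSet`
interface.

## Angle composition

A prescription "α anterior (axial), γ proximal (coronal)" is turned into a
direction by the **projection convention** (default):

    d ∝ ml + tan(α)·ap + tan(γ)·si

This is the unique direction whose projection onto the axial plane makes α
with ML *and* whose projection onto the coronal plane makes γ with ML —
i.e. what a surgeon reads simultaneously off the two CT planes. The
alternative **sequential convention** (rotate anteriorly by α within the
axial plane, then elevate by γ) is implemented behind the same switch; the
two coincide whenever either angle is zero and differ by ≈ 3.4° at 30°/30°.
Published prescriptions rarely state which composition they mean; exposing
both makes the ambiguity explicit. The inverse (`angles_from_direction`)
is exact to 1e-9 over (−60°, 60°)² and rejects directions that do not point
into the bone (ML component ≤ 0).

Default prescriptions: LCL 30°/0° (∅8 × 25 mm), PT 30°/30° (∅8 × 25 mm),
MCL 30°/30° (∅7 × 25 mm), POL 30°/30° (∅7 × 25 mm). Named presets carry the
literature alternatives for the lateral tunnels (35° anterior; 20°/10°).
The PSI guide itself is represented only by its descriptive parameters
(2.5 mm K-wires, 0.6 mm cannula clearance, 0.4 mm bone offset, 3.3 mm mean
shell thickness): its computational content is the cannula direction, which
equals the planned tunnel direction.

## Tunnel convergence

Tunnels are capped cylinders (entry, unit direction, diameter, 25 mm
depth). Pairwise convergence uses the exact clamped closed-form minimum
distance between the two axis segments; the reported wall thickness is that
distance minus both radii, and a pair "collides" when the wall is thinner
than a configurable margin (default 0 mm: touching). Cross-side pairs are
checked too. The kernel is verified against a refining grid-sampling oracle
to 0.01 mm.

## Registration

The post-operative mesh is overlaid on the pre-operative one by ICP:

- correspondences are **point-to-surface** (source vertex to the nearest
  point on any target triangle), found by a k-candidate KD-tree search over
  triangle centroids with a radius-bound fallback that makes the result
  exact;
- a fixed random subsample of ≤ 5,000 source vertices (2,000 in the study
  pipeline) keeps each iteration cheap and, because the subsample is fixed,
  the correspondence objective non-increasing;
- the rigid step is the SVD (Kabsch) least-squares solution with reflection
  correction, re-solved from the original sample each iteration;
- initialization is centroid alignment (sufficient for the moderate
  repositioning between two scans of the same bone: ≤ 15–20°, ≤ 10 mm);
- convergence: change in mean closest-point distance < 1e-4 mm, at most
  100–200 iterations, with explicit failure (never silent) otherwise.

The reported residual is the mean vertex-to-surface distance at
convergence. On noiseless displaced copies the recovered transform is
accurate to well under 0.1° / 0.1 mm, and with 0.3 mm isotropic vertex
noise the residual settles near the half-normal expectation
σ·√(2/π) ≈ 0.24 mm — the regime of the sub-millimetre overlay residuals
commercial ICP reports for same-bone scan pairs.

## Accuracy endpoints

Angular deviation is the plain 3D angle between planned and achieved unit
directions. The clinical phrasing "measured in the plane where the
deviation is greatest" is exactly this quantity: the angle between two
vectors projected into any plane is maximal in the plane they span, where
it equals the 3D angle (projection can only shrink an angle). Directions
are compared signed — a reversed drill is 180°, not 0°. Entry-point
distance is the Euclidean distance between entry points after the achieved
tunnel is mapped through the registration transform. Both metrics are
invariant under a common rigid transform (tested).

## Error simulation

Each (technique, ligament) cell of the error model is summarized by
(median, Q1, Q3) for both outcomes; the packaged defaults are the observed
per-ligament accuracy summaries of a 5-vs-5 cadaveric comparison of
freehand vs PSI drilling. A two-parameter log-normal is the minimal
strictly-positive family identified by such a summary:

    μ = ln(median),   σ = ln(Q3/Q1) / (2 z₀.₇₅),   z₀.₇₅ = 0.67449

This pins the median and the quartile **ratio** Q3/Q1 exactly; the implied
individual quartiles are median·(Q3/Q1)^{±1/2}, which coincide with the
configured ones exactly when those are log-symmetric about the median (true
to ~1% for most cells). A degenerate cell (Q1 = Q3) is a point mass.

Execution: the drawn angular magnitude tilts the planned direction at a
uniformly random azimuth (cone model); the drawn entry magnitude slides the
entry along a uniformly random surface-tangent direction and re-projects it
onto the bone (curvature makes the realized offset slightly smaller than
the draw; the recorded ground truth is the realized offset). Angular and
entry errors are independent, and independent across the four tunnels of a
knee — no correlation structure is published for the protocol being
emulated, and this is the conservative default. Freehand errors
stochastically dominate PSI errors over the working quantile range
(5th–95th percentile) for every ligament; with strongly unequal σ the
log-normal families can cross in the extreme upper tail (beyond the ~99th
percentile for the POL cell), which is why dominance is asserted over the
working range rather than pointwise everywhere.

`simulate_study` runs the full pipeline per knee — generate femur, plan,
perturb, rigidly reposition (rotation 5–15°, translation ≤ 10 mm per axis),
optionally noise, register by ICP, measure — and keeps injected ground
truth beside the measured values. With zero surface noise the measured
errors reproduce the injected ones to < 0.05° / 0.05 mm end to end; this is
the pipeline's core correctness surface. A master seed spawns per-knee
substreams, so runs are bit-reproducible at the record level.

## Synthetic femur

The generator blends four implicit primitives — lateral and medial condylar
ellipsoids (semi-axes 19/24/21 mm, centers ±21 mm), a trochlear bulge, and
a diaphyseal cylinder (radius 15 mm) — with a log-sum-exp smooth minimum
(blend radius 6 mm), and polygonizes the zero level set by marching cubes
(default pitch 1.25 mm; tests use 2.0–2.5 mm). Nominal epicondylar width is
80 mm, in the adult range; a seeded ±3% jitter of condylar geometry and a
global `size_scale` provide inter-specimen variability (no size statistics
are published for the emulated specimens, so these are the package's own
defaults). Scaling is applied to the finished model, so similarity is
exact. Non-watertight polygonization fails loudly.

Footprints are placed at parametric epicondylar offsets and projected
exactly onto the surface. The LCL–PT footprint separation is calibrated to
the ≈ 18.5 mm that anatomic studies report for the LCL and popliteus
femoral attachments; with that separation the four default tunnels never
collide (wall ≈ 0.4–1.4 mm across seeds — tight, which is precisely why
the angulation prescriptions exist), while visibly closer footprints would
produce LCL–PT convergence.

What the synthetic femur does **not** model: cortical/trabecular interior,
CT intensity or segmentation error (surface noise is a single isotropic
Gaussian stand-in), cartilage, osteophytes, and true anatomic shape
variation beyond affine size and mild condylar jitter. Passing tests
therefore demonstrate the correctness of the computational pipeline under
known ground truth, not the clinical accuracy values themselves, which are
taken as calibration inputs.

## Statistics

- **Summaries**: median and quartiles, linear-interpolation convention by
  default (Tukey hinges available; the conventions agree when
  n ≡ 1 mod 4, e.g. at the per-ligament n = 5).
- **Mann–Whitney**: U from rank sums (midranks under ties). When the pooled
  sample is tie-free the two-sided p is **exact**, from the full null
  distribution of U computed by the classic counting recurrence
  (equivalent to enumerating all C(n_a+n_b, n_a) group labelings); this
  covers both the 5-vs-5 and the pooled 20-vs-20 comparisons. Two-sided
  convention: p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). The attainable
  minimum at 5 vs 5 is exactly 2/252 ≈ 0.0079, printed as 0.008 — which is
  why complete separation in every per-ligament angular comparison prints
  identically. With ties, the midrank normal approximation with tie and
  continuity correction is used and flagged.
- **Levene**: classic (center = mean) by default, since that is what plain
  "Levene" denotes; Brown–Forsythe (center = median) behind the same
  interface. Zero within-group spread in both groups makes the statistic
  undefined and raises; `compare_study` converts that to a NaN cell with a
  warning so the table shape survives degenerate strata.

## Problem sizes and determinism

The acceptance script uses the calibrated-draw layer only (no meshes):
1,000 replicates for each pooled-median mean and 200 replicates for the
significance percentile, which gives Monte-Carlo noise well inside the
quantities' tolerances in a few seconds. The test suite runs the mesh
pipeline at 2.0–2.5 mm pitch with 2 knees per group for end-to-end checks.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-knee substreams make any single knee
reproducible in isolation.

## Known limitations

- The frame construction is a surrogate, not a reimplementation of any
  specific published CT protocol; absolute angle values depend on it, while
  planned-vs-achieved *deviations* (the accuracy endpoints) are largely
  insensitive to the frame choice.
- The angle-composition convention of published prescriptions is ambiguous;
  both interpretations are provided, differing by a few degrees at oblique
  prescriptions.
- Error draws are independent across tunnels and outcomes; real surgical
  error plausibly correlates within a knee, which would widen the sampling
  distribution of per-knee summaries.
- Tunnels are straight capped cylinders; drill wander, cortical breach
  shape and tunnel-wall blowout are out of scope, as are tibial and
  cruciate tunnels.
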