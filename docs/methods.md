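# Methods

This note documents the models, estimators, parameter choices, and known
limitations of mechanoquant. All lengths are in µm, all angles in degrees
counterclockwise from the image x-axis, wrapped to [−90°, 90°) (axial
data). Pixel coordinates are 0-based (row, col); subpixel positions are
real-valued (row, col).

## Segmentation chain

Organoids are separated from background by Otsu thresholding of the
Gaussian-smoothed (σ = 2 px by default) sum of the K8 and K14 channels,
followed by hole filling and removal of components below 500 px². The
threshold is always computed from the image, so segmentation is invariant
to a global positive intensity gain.

Nuclei are found inside each organoid mask by a two-class intensity model:
k-means with k = 2 on the smoothed DAPI values within the mask, taking the
brighter class as nuclei. Touching nuclei are split by a watershed seeded
on smoothed-intensity maxima (minimum seed separation 4 px); fragments
below 20 px² are absorbed into their largest neighbor. The two-class model
keeps nucleus detection gain-invariant as well.

Cells are obtained by a marker-based watershed seeded on the nuclei. The
elevation surface is a multi-scale Hessian ridge enhancement (Sato
tubeness, maximum over scales σ ∈ {1, 2, 4} px) of the K8+K14 sum, so
cell–cell membranes act as ridges. The watershed uses a small compactness
term (0.05): on elevation plateaus — notably the band just inside the
organoid boundary, where the rim's intensity step produces a ridge ring
with a flat outside — a plain watershed floods the whole plateau from
whichever basin breaks through first, which assigned most of the boundary
band to a few cells. The compactness term resolves plateaus by geodesic
proximity to the seeding nucleus instead. Cell regions partition the
organoid mask exactly, and each cell contains exactly one nucleus.

A cell is *outer* iff its region shares at least one pixel with the 1-px
inner boundary band of the organoid mask (literal contact with the
surrounding matrix); classification is purely geometric. Masks and labels
use 8-connectivity throughout.

## Yap quantification

The per-cell ratio is (nuclear mean − b)/(cytoplasmic mean − b) on the Yap
channel, where the cytoplasm is the cell region minus its nucleus. The
background b is the median intensity outside all organoid masks dilated by
10 px — the median is robust to stray debris, and the dilation keeps the
organoid's own blur out of the estimate. When the cytoplasmic mean does
not exceed b the ratio is undefined; such cells are flagged invalid and
excluded from group summaries rather than given a number. The ratio is
invariant to a gain applied to the Yap channel, and to an intensity offset
when the background is re-estimated.

K14 Hi/Lo: a cell is Hi iff its mean K14 intensity over the cell region
strictly exceeds the mean of those means over the outer-layer cells of the
same image; ties are Lo. The threshold population is the outer layer
because that is the rim population the classification is used to compare.

Rim vs leader: inner cells get role `none`; outer cells are `rim` unless
both elongated (major/minor axis ratio ≥ E_min = 2.0) and protrusive
(farthest boundary point ≥ P_min = 5 µm beyond the organoid's convex body
outline). The body outline is the convex hull of the organoid mask after a
morphological opening of radius 5 µm, which strips thin protrusions so a
leader's own process does not inflate the hull. Leader selection in
practice is done by eye; these thresholds are a reproducible surrogate and
are configurable.

Cell length is the longest geodesic path on the skeleton of the cell
region (8-connected steps weighted 1/√2, endpoints found by a double-sweep
shortest-path search, plus one pixel for the two half-pixel end caps). The
skeleton of a round region collapses to a short segment, so lengths are
meaningful for elongated cells only — the intended use.

## Fiber orientation and the order parameter

Orientation and coherency come from the structure tensor: Gaussian
derivative gradients at σ_grad = 1 px, tensor products smoothed with
σ_window = 4 px. θ is reported for the fiber axis (eigenvector of the
smaller eigenvalue); coherency is (λmax − λmin)/(λmax + λmin) ∈ [0, 1].
Pixels whose gradient energy is below 1e−6 of the image maximum energy are
invalid — on a constant image every pixel is invalid and no angle is
reported.

The scalar order parameter of an angle sample is
S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²), the eigenvalue magnitude of the 2 × 2
second-order orientation tensor; averages may be weighted. S is
rotation-invariant, 180°-periodic, 0 for uniform axial angles, and 1 iff
all weighted angles coincide mod 180°.

Rim analysis anchors 30 × 50 µm rectangles on the organoid boundary
contour at a fixed arclength spacing, long axis along the outward normal
(from the local contour tangent over a ±6-point window, oriented away from
the centroid), with distance zero at the cell–matrix interface. Valid
pixels within 50 µm of the interface enter the per-ROI sample. By default
angles are weighted by coherency squared: plain coherency weighting is the
conventional choice, but partially coherent pixels — fiber crossings,
where the window averages two orientations and biases S upward, and fiber
tips, whose end-cap edges point across the axis and bias S downward —
carry intermediate coherency, and squaring suppresses them harder. The
exponent is configurable (1 restores plain weighting, 0 plus
`weight_by_coherency=False` disables weighting). A ROI with no valid
pixels reports a missing value, never S = 0. The angle between a ROI's
mean orientation and the rim normal is reported separately; S itself stays
rotation-invariant.

For a von Mises model on the doubled angle with concentration κ, the
population order parameter is S = I₁(κ)/I₀(κ); the package inverts this
Bessel ratio to estimate κ̂ from a measured S.

**Known limitation.** At high concentration (κ ≈ 8, S ≈ 0.94) the
image-based measurement systematically underestimates S by ~0.01–0.04:
fiber-tip pixels contribute off-axis angles that survive any fixed
coherency weighting. Because dS/dκ is small there, κ̂ inverted from an
image-measured S is reliable at low-to-moderate concentration (within 15%
for κ ≤ 2 in the test suite) but not at κ ≈ 8; concentration recovery at
high κ is validated on the generator's stamped-angle samples instead.

## Protrusive index

Pipeline: Gaussian blur (σ = 2 px) → threshold (Otsu unless given) →
binary erosion (2 iterations) → largest 8-connected component. The
perimeter is measured on a marching-squares contour of the lightly
smoothed (σ = 1 px) mask: contours of raw binary masks overestimate
perimeters by a direction-dependent ~5% staircase bias, which would
inflate the index of even a perfect disk. The index is the boundary
perimeter divided by the convex-hull perimeter — a ratio of perimeters,
not areas, so it is dimensionless, equals 1 for convex shapes, and grows
with protrusion depth. Area growth is a plain µm² area ratio between two
masks. Strand metrics measure given polylines (exact arc length) or label
masks (longest skeleton path); strand identification is an input, not an
inference.

## Bead displacement

Drift is estimated by subpixel phase correlation (upsampling factor 20).
The default registers every frame directly against frame 0, because
chaining consecutive-pair estimates accumulates a random walk of
~0.1–0.2 px per step that propagates into end-to-end displacements; the
consecutive mode remains available for long movies whose scene
decorrelates from the reference frame.

Detection runs on drift-corrected frames after subtracting the temporal
10th percentile of the corrected stack (the static scene): beads move
between frames, gel texture does not. Spots are local maxima of a
difference-of-Gaussians bandpass (σ and 4σ, σ = 1.5 px) above half the
99.9th-percentile response — a robust scale, so one bright overlapping
pair cannot mask the other beads — refined by center of mass. Linking is
mutual-nearest-neighbor within a 10 px gate; a detection with a competing
candidate inside the gate is flagged ambiguous. Any track missing a frame
is incomplete.

Inclusion follows the geometric rules: complete track, initial distance to
the organoid border at most one diameter (mixed organoids) or radius
(luminal organoids), and not within the selection distance of two
organoids simultaneously. Distances are measured to the border contour,
not the centroid. Displacement toward the organoid is initial minus final
border distance (positive = toward); a path-integrated variant accumulates
only the inward steps. Displacement of a bead under pure radial advection
equals speed × (n_frames − 1) because n frames span n − 1 intervals.

## Synthetic data

The generators emulate only the statistics the analysis consumes; they are
not photorealistic and are strictly 2D (analyses target mid z-sections).
All randomness flows from `numpy.random.default_rng(seed)`; identical spec
and seed give bit-identical outputs.

* **Organoid**: cells are a Voronoi tessellation of a disk seeded with one
  evenly spaced rim ring (single-cell outer layer) plus a jittered
  hexagonal interior packing; nuclei are filled discs of 0.45 cell radii.
  Default geometry 50 µm organoid radius, 7 µm cell radius, 16 rim cells
  at 1 µm/px — a mid-section of a small organoid. Channel levels (DAPI
  200, K8 120, K14 170/40 for Hi/Lo, Yap cytoplasm 60 over background 10)
  give the strong nuclear counterstain and bimodal K14 contrast typical of
  such imaging. Per-cell Yap ratios are set by role (`rim`/`inner`/
  `leader`); before noise the rendered background-subtracted ratio equals
  the specified value exactly. The K14-Hi count among rim cells is exactly
  `round(fraction × n_rim)`. Optional leader cells are radial bars
  (elongation ≳ 3) protruding 15 µm beyond the disk. Noise is additive
  Gaussian clipped at 0 — the simplest model sufficient for recovery
  tests; it omits photon-count scaling, optics blur, and intensity
  gradients, so passing tests demonstrate correctness of the estimators,
  not robustness to every confocal artifact.
* **Fibers**: straight rectangles of length 15 µm and width 2 px stamped
  at uniform positions; axial angles drawn via 2θ ~ vonMises(2µ, κ), so
  the stamped sample's expected order parameter is I₁(κ)/I₀(κ). A radial
  mode points each fiber along the radius from a given center. Real
  collagen networks have curved, branching, cross-linked fibers; the
  generator reproduces only the orientation statistics.
* **Beads**: point sources (Gaussian σ 1.3 px) advected radially toward
  the organoid at constant speed, stopping at the border, over a broad
  (σ = 5 px) static speckle texture standing in for the gel; the whole
  scene is translated by the cumulative stage drift, generated on a padded
  canvas so no content wraps at the frame edge. Ground truth keeps drifted
  and drift-free positions; beads leaving the frame are flagged, never
  dropped.
* **Borders**: star polygons r(φ) = base + depth·(1 + cos nφ)/2 sampled at
  720 vertices; the exact polygon perimeter and convex-hull perimeter are
  the ground truth. Strand fixtures are polylines with exact arc length.

## Problem sizes in the test suite

The acceptance tests run the von Mises recovery on 2048² px frames with
5000 fibers per κ ∈ {0.5, 2, 8}; Yap recovery on ten ~35-cell organoids
spanning true ratios 0.5–4 at 5% noise; segmentation invariants on 20
seeded organoids; the hull-perimeter law on 100 random blob masks; and
bead recovery on 300–360² px movies of 10–11 frames with 15–20 beads.
These sizes put every sampling-limited check well inside its tolerance
while keeping the full suite under a minute on a laptop-class machine.
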