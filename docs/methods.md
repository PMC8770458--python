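# Methods

`mitomorph` implements the quantitative core of a 3-D cardiac mitochondrial
morphometry study: per-organelle measurements on segmented block-face SEM
label volumes, unbiased stereological density estimation, and 2-D TEM-style
cristae analysis, together with a synthetic-data generator that stands in
for the microscope. This note records the models, the estimators, the
numerical choices, and what the synthetic validation does and does not show.

## The phantom: synthetic cardiomyocyte volumes

No public EM volumes accompany the study this pipeline re-implements, so
every estimator is validated against seeded phantoms with exhaustive ground
truth.

**Geometry.** A volume is a `(z, y, x)` raster at an anisotropic voxel pitch
(default 13.5 × 13.5 × 50 nm, the block-face SEM acquisition geometry). Two
sarcolemma bands bound the cell in y (with a 2-voxel extracellular margin
outside each); an ellipsoidal nucleus, elongated along the fibre (x) axis,
sits at the centre. Subsarcolemmal mitochondria (SSM) are laid in strands
abutting the bands; interfibrillar mitochondria (IFM) fill strand-like rows
separated by unlabeled myofibril slabs; perinuclear mitochondria (PNM) walk
a cursor around the nuclear envelope so each touches it. All objects are
strictly disjoint, keep one voxel clear of the raster boundary, and keep at
least a two-voxel gap to the context mask of the *other* subtypes, so the
spatial classification of every object is unambiguous by construction.

**Body primitive.** Bodies are randomly oriented superellipsoids
(`|x/a|^p + |y/b|^p + |z/c|^p <= 1` with the exponent `p` drawn uniformly in
[2, 3]) with a rod-like aspect: longest along the fibre axis, flattest along
the cutting axis. Two considerations force this beyond a plain ellipsoid:
cardiac IFM are visibly brick- or rod-shaped, and — decisively — disjoint
ellipsoids at the study's mean body volumes (7.2–7.3 × 10⁸ nm³ for SSM/IFM)
cannot reach a 30% volume fraction inside a 2.4-µm-deep slab at all; the
packing ceiling of the row layout is about 27%. Rounded bricks pack past the
target with margin. The "irregular" shape class adds a random low-order
real spherical-harmonic radial perturbation (degrees 2–3, amplitude = the
maximum fractional radial excursion; defaults 0.05 for oval, 0.30 for
irregular). Tubular projections are capsules appended at the body surface
along a mostly in-plane direction; a nanotunnel is two bodies joined by a
capsule, emitted as one label.

**Ground truth.** Volumes are exact voxel counts. Surface areas of
appendage-free bodies are computed by numerical integration of the
parametric radial surface (cross-validated against the Knud Thomsen ellipsoid
approximation at `p = 2` in the test suite); this covers the perturbed irregular
class too. Projection truth is the capsule length from body surface to tip
and twice the capsule radius; nanotunnel truth is the surface-to-surface
tube length and diameter. The volume-level true fraction is the exact
mitochondrial voxel count over the cardiomyocyte (interior) voxel count, and
subtype shares are exact voxel shares.

**Budget filling.** Each subtype is filled to its voxel budget
(`target_mito_fraction × subtype_mix`); body volumes are drawn lognormally
(CV 0.25 by default) around the subtype means, the final object of a
subtype is resized to close the residual, and an object that finds no home
is redrawn smaller (×0.7 steps) — the small-body tail of the distribution
fills residual gaps. Realized fractions land within ~0.3 percentage points
of target; realized subtype shares within ~1 point. A volume that cannot
hold the request raises a capacity error rather than silently
under-delivering; with wild-type defaults the minimum practical raster is
about 640 × 640 × 48 voxels.

**Defaults are the wild-type study conditions**: total fraction 0.302;
subtype mix 15.3 / 80.1 / 4.7% (SSM/IFM/PNM); IFM oval fraction 0.69;
projection length/width distributions per subtype (e.g. SSM 0.574 ± 0.415 µm
long, 0.220 ± 0.068 µm wide); mean body volumes 7.23/7.29/3.70 × 10⁸ nm³;
nanotunnel dimensions drawn from 1.1–1.91 µm × 0.28–0.33 µm. Where the
source reports no number (oval fractions of SSM/PNM, projection
probabilities, myofibril slab width, nucleus size) the defaults are chosen
once at values plausible for ventricular myocardium and exposed as
parameters. Shape classes are allocated by an online largest-remainder rule
(exact counts, not Bernoulli draws), and projection lengths are floored at
0.26 µm — just above the morphometric detection threshold — so every true
projection is recoverable.

**What the phantom does not emulate**: acquisition physics (charging,
curtaining, noise), membrane ultrastructure in 3-D, genuinely interconnected
mitochondrial networks, segmentation errors, or regional heterogeneity of
the myofibril/mitochondria partition (exposed as a free parameter instead).
Passing recovery tests therefore demonstrate estimator correctness on
idealised geometry, not robustness to segmentation noise.

## Morphometry

* **Volume** is the exact voxel count times the voxel volume.
* **Surface area** comes from a marching-cubes iso-surface of the lightly
  smoothed (σ = 0.8 voxel) binary mask at level 0.5, in physical
  coordinates. Smoothing suppresses the staircase overestimate that raw
  voxel faces give (~1.5× for smooth bodies). Digital spheres and cubes land
  within 5% of the analytic areas; generated anisotropic bodies carry a
  small positive systematic from the 50-nm z staircase, inside the 10%
  batch contract.
* **Subtype assignment** dilates the object by `contact_tolerance + 1`
  voxels (full 26-connectivity) and tests overlap with the sarcolemma and
  nucleus masks: sarcolemma ⇒ SSM, nucleus ⇒ PNM, both ⇒ `excluded`
  (merged subpopulations are not scored), neither ⇒ IFM. A ≤ 1-voxel gap
  counts as "directly adjacent".
* **Shape classification** first strips projections by a morphological
  opening (Euclidean, radius 180 nm — above the largest projection radius,
  below body scale), then scores the body alone: Jaccard overlap with the
  moment-matched ellipsoid (semi-axes √(5λᵢ)) and convex-hull solidity
  (point-cloud hull with a half-voxel shell correction). `oval` requires
  overlap ≥ 0.875 **and** solidity ≥ 0.92. The source classification was
  visual; these thresholds were calibrated once against 120 generator
  bodies at the default amplitudes (clean separation) and frozen.
  "Has a tubular projection" is an orthogonal flag, matching the overlapping
  third category of the original scheme.
* **Skeleton operations** resample each object's bounding box to an
  isotropic 27-nm pitch (nearest-neighbour) before 3-D skeletonisation —
  the topology is computed in voxel space, so the ~3.7× z anisotropy must be
  removed first — while all widths are read from the native-grid anisotropic
  Euclidean distance transform and all lengths from physical coordinates.
* **Projections** are skeleton endpoints outside the opened body whose
  geodesic path to the body (multi-source Dijkstra, chord-smoothed over
  3-node steps) is at least 0.25 µm long and whose median local diameter is
  at most half the body equivalent diameter. Length adds the distance
  transform at the endpoint (the skeleton stops about one radius short of
  the tip) plus an analytic fillet correction,
  `1.05·r_open − sqrt(r_open² − r_tip²)`, for the opened body's protrusion
  into the projection root (the projection shields the body surface from
  the erosion). Tip width is twice the distance-transform maximum over a
  short window three nodes from the free end ("measured close to the
  furthermost tip"). Mean recovered length on capsule populations sits well inside the 10%
  contract; tip widths inside their 20% contract.
* **Nanotunnels**: within a label, thick skeleton nodes (local diameter
  above the 0.4 µm tunnel cap) cluster into candidate bodies; a thin
  skeleton stretch joining two clusters is a tunnel if the path between the
  reconstructed body surfaces is ≥ 1.0 µm long, its median diameter is under
  the cap, and both bodies' equivalent diameters are at least twice the
  tube diameter. Dumbbell phantoms recover length within the 10% contract; the diameter
  reads slightly low (z-quantisation of a 0.3-µm tube at 50-nm sections)
  but within the tested band.

## Stereology

**Volume fraction.** Two square lattices are overlaid on every
`slice_interval`-th section (default 20, i.e. 1 µm): a fine green lattice
(2.674 × 10⁶ nm² per point) scored against mitochondrion labels and a
coarse red lattice (13.368 × 10⁶ nm² per point) scored against the
cardiomyocyte mask. The fraction is

    Vv = [N_mito · a_green · (n_slices · t)] / [N_cm · a_red · (n_slices · t)] × 100

with the slice term retained verbatim even though it cancels. Random
placement draws a uniform lattice offset per region *and* a uniform random
start for the systematic slice series — the latter matters in any volume
with z structure (the phantom's body layers; real myocardium's
z-periodicity is milder). Per-object edge exclusion (objects touching the
left or bottom border of the counting box) is implemented and on by
default; the default regions are three full-frame depth bands, where the
forbidden borders coincide with the raster boundary and no generated object
lies, so the rule is exact but vacuous — sub-frame boxes activate it.

Counts should be pooled (summed) across regions before applying the ratio
when frames are small: the ratio of means is unbiased, while the mean of
per-region ratios carries a Jensen bias of order `1/N_cm`. Pooled estimates
on phantom volumes stay inside a 0.5-percentage-point bias bound over
hundreds of placements; the per-region mean ± SD remains available for protocol
fidelity.

**Subpopulation shares** reuse the same green counts keyed by a
label→subtype map and report percentages of total mitochondrial points;
regions are expected to contain a nucleus when PNM are scored (recorded as
region metadata, not enforced).

**Cristae surface density.** A tile lattice carries one test point and one
line probe (length = l/p) per tile; the estimator is the classical
line-intercept form `Sv = 2·ΣI / (l/p · ΣP)`. Intersections are counted as
transits of the *skeletonised* membrane centre-lines with sub-pixel gap
bridging (2.5 px): counting against thick binary membranes or raw
8-connected staircases inflates I by 30–50% through grazing and
corner-splitting. Isotropy comes from a random probe orientation per
placement. On lamellar phantoms with analytically known membrane length per
area the estimator sits within the 10% band around `(4/π)·B_A` (the residual
positive bias comes from tangent hits), and doubling the true lamellar
density doubles Sv within the same band.

## Cristae images and measurements

**Generator.** A TEM-style 8-bit image (2 nm/px default): light matrix, dark
elliptical boundary, and parallel membrane doublets at a random in-plane
orientation. Each crista is two uniform membrane lines; the landmark
convention is fixed throughout the package: **W_O** is the outer-edge to
outer-edge width of the doublet, **W_I** the lumen between the inner
membrane edges (so each leaflet is `(W_O − W_I)/2` thick — 10 nm at the
36/16 nm defaults), and **S** the edge-to-edge gap between consecutive
doublets. (Centre-to-centre landmarks are arithmetically inconsistent with
36/16 nm and are not used, though a centre-to-centre spacing is also
reported.) Rendering is antialiased; mild Gaussian blur (σ = 1 px) and
additive grey noise (σ = 8 levels) follow. Quality classes 1/3/5 are
realised as ordered-lamella coverage of the interior (1.0 / 0.5 / 0.0 of
the area by default).

**Measurement.** Global Otsu threshold (membranes dark); grey profile
sampled at 0.5-px steps along a line (auto-oriented along the lamella
normal in the synthetic scenes); membrane peaks found on the inverted
profile at 25%-of-range prominence with parabolic sub-sample refinement;
peaks closer than 30 nm pair into doublets (within-doublet peak separation
is ~26 nm at default geometry, across-gap separation ~38 nm); outer and
inner edges are the half-prominence crossings. W_O/W_I recover the rendered
truth within the tested 2 nm (sub-nanometre in the mean in practice);
errors grow monotonically with noise.
The quality score thresholds coverage at 0.70 (score 1) and 0.20 (score 5),
with elongated components (axis ratio ≥ 4, length ≥ 60 nm) counting as
ordered lamellae and coverage measured within a 40-nm reach of them.
Mitochondria scored 3 or 5 are excluded from surface-density and width
batches, mirroring the original "clearly defined cristae" inclusion rule.

## Reporting

The unit of replication is the animal: records are averaged per animal
first, and group mean, SD and SEM (= SD/√n) are computed over animal means
(n = number of animals; a single-animal group is flagged with undefined
SEM). Fold changes are ratios of group means. Comparisons: unpaired
two-tailed Student t (pooled variance; degenerate zero-variance identical
groups return t = 0, p = 1 rather than NaN), one-way ANOVA with Tukey HSD,
and two-way ANOVA (type-II, with interaction) with Sidak-adjusted pairwise
contrasts of the primary factor within each level of the secondary
(`p_adj = 1 − (1 − p)^m`). Significance is reported at P < 0.05. The layer
delegates to scipy/statsmodels and is cross-checked against pingouin in the
test suite. Tables serialise to CSV/JSON with a provenance block (package
version, caller-supplied seeds/config).

## Problem sizes used in validation

Recovery tests run at deliberately modest rasters chosen to keep the
signal-to-tolerance ratio comfortable: the shared wild-type volume is
640 × 640 × 48 voxels (~90 mitochondria, matching the per-subtype sampling
scale of the original segmentation), classifier recovery uses 300 bodies,
cristae recovery 20 images, and the acceptance script regenerates a
1024 × 1024 × 96 volume for the volume-fraction target. Estimator SDs
quoted above refer to these sizes; larger volumes tighten them roughly as
1/√(points counted).

## Known limitations

* Surface areas of flat anisotropic bodies carry a small positive bias from
  the 50-nm z staircase; absolute SA comparability with mesh-based tools
  that smooth differently is limited, internal consistency is not.
* The projection detector misses projections shorter than ~0.27 µm (floor +
  discretisation) and occasionally splits or truncates one on highly
  perturbed bodies; batch statistics are robust, single-object calls on
  pathological shapes may not be.
* The Sv probe carries a small positive residual from tangent hits on
  curved centre-lines; it is stable across densities, so ratios (the quantity the
  original comparison uses) are unaffected.
* The two-way ANOVA requires a full factorial with every cell occupied; no
  mixed-effects or unbalanced-design machinery is provided.
* Quality scoring assumes lamellar (not tubular/vesicular) cristae texture.
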