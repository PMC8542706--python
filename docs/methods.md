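# Methods

`tavrseal` reproduces, at desk scale and on fully synthetic anatomy, the
analysis chain used to study sealing behavior of a self-expanding
transcatheter aortic valve in bicuspid (BAV) versus tricuspid (TAV) aortic
roots: virtual device deployment, skirt apposition/malapposition
quantification per anatomical region, frame-deformation measurement, and
the cohort statistics comparing the two morphologies.  The clinical imaging
data behind the original analysis are access-restricted, so every input
here is generated by the package itself; what the pipeline demonstrates is
the *mechanistic chain* (dysmorphic interleaflet triangles → local skirt
gaps → higher interleaflet malapposition in BAV), not patient-level
numbers.

## Synthetic aortic root

The root is an open tube around the z-axis: annular plane at z = 0, +z
aortic, angle θ measured from a fixed commissure, lengths in mm.  The inner
surface carries per-triangle region labels (LVOT, leaflets, interleaflet
triangles, ascending aorta) and material ids (wall, leaflet tissue,
calcium).  Key shape rules:

* The annular cross-section is an ellipse (`annulus_dmax`, `annulus_dmin`)
  whose axes sit at a per-patient random angle to the commissures.  The
  section blends linearly to an area-equivalent circle at the commissure
  level — an elliptical LVOT/annulus and near-circular sinotubular junction,
  as in real roots.
* Leaflets are modeled as part of the tube surface: a band from the annulus
  to the commissure level (18 mm), bulged inward by up to 0.4 mm.  The
  sealing analysis only needs the innermost surface the skirt can face, so
  free leaflet shells are not modeled.
* Interleaflet triangles are outward wall recesses in angular wedges at the
  commissures (base half-width 35% of a sector, tapering to the apex).  The
  recess depth is the central dysmorphism parameter: normal TAV triangles
  are nearly flush fibrous walls (depth 0.5 ± 0.3 mm, truncated to
  [0, 1.2]); the surviving triangles of bicuspid roots are underdeveloped
  and recede further (2.0 ± 0.5 mm, truncated to [0.8, 3.5]).  The recess is
  near-uniform across the wedge (effaced along its whole height and width),
  tapering only at the rim.
* Morphologies: TAV has three leaflets/triangles at 120°; Sievers type 0
  BAV has two at 180° (one triangle congenitally absent); type 1 BAV has
  three developmental leaflets with the θ = 0 commissure fused by a raphe —
  an inward ridge of configurable height — and its triangle relabeled as
  leaflet tissue.
* Calcium deposits live on leaflet triangles.  A deposit with volume V and
  protrusion p claims the leaflet triangles nearest its center until their
  area reaches V/p, then displaces them inward by the uniform depth
  V/area, so footprint × depth reproduces V exactly.  Deposits never
  overlap; heavy burdens are split into several nodules so no deposit can
  obstruct the crimped device.

Default mesh resolution is 96 × 60 (≈11.5k triangles): fine enough that
annular metrics converge to <1%, small enough that the brute-force
ray-casting oracle runs in seconds.

## Synthetic cohort

`sample_cohort` draws 17 TAV / 11 BAV0 / 15 BAV1 patients (the study group
sizes) from truncated normal covariate distributions parameterized by the
published group means/SDs: annulus diameters, calcium volume
(100–2500 mm³; higher burden in BAV), implantation depth (0–14 mm), and an
age-like covariate.  Only summary statistics of the source population are
available, so truncated normals are the simplest faithful choice.  Device
size is the smallest of {23, 26, 29, 32} with sizing index
(size / perimeter-derived diameter) ≥ 1.0.  A single master seed spawns
independent per-patient substreams (`numpy.random.SeedSequence`), making
cohort tables byte-identical under a fixed seed.

## Device frame and skirt

The proprietary strut geometry of the clinical device is not public; a
generic diamond-cell lattice (24 levels × 32 sectors, ≈2500 strut + skirt
elements, matching the reference model's element count to order of
magnitude) follows a flared nominal profile whose maximum diameter equals
the size label at the inflow.  The skirted inflow (lower 40% of the 50 mm
height) is near-cylindrical (≥0.95 of the inflow radius), with the waist
above the skirt — on the clinical device the sealing zone is likewise
cylindrical, with the constriction higher up for coronary access.  The
fabric skirt is the set of quadrilateral cells below the skirt height.

Radial response is a per-level linear hoop law:
F(d) = k · Σ_levels max(0, (R_l − d/2)/R_l), with k = 20 N per level at
unit strain and a multiplicative unloading factor 0.85 (loading/unloading
hysteresis).  No experimental bench data are public, so stiffness and
hysteresis are configuration, and only curve-shape properties (zero at
nominal, monotone, unloading ≤ loading) are asserted.

## Deployment

Full frictional finite-element contact is replaced by per-node radial
equilibrium:

1. The frame is crimped to 8 mm and positioned coaxially with its
   ventricular end at z = −depth (depth prescribed; the original workflow
   likewise iterates placement until the observed implantation depth is
   matched, so no axial slip is simulated and the friction coefficient 0.7
   is recorded but unused).
2. Each node's luminal wall radius, region and material are sampled by a
   horizontal ray from the axis (Möller–Trumbore against all triangles).
3. Levels are released sequentially from the ventricular end.  After each
   release, damped-Jacobi iteration (damping 0.5) drives every released
   node to equilibrium between: frame expansion pressure
   C_l·(R_l − r)/R_l (C_l from the hoop stiffness spread over the level's
   surface), a linear contact penalty k_t·δ with
   k_t = E·t/r² (thin-shell stiffness) capped at the yield stress for
   calcium (perfect plasticity), and coupling springs on the radial
   deviation from the nominal profile — 0.15 MPa/mm between adjacent
   sectors (ring-bending proxy: the lattice bridges narrow recesses rather
   than ballooning into them, which is exactly the mechanism that keeps the
   skirt off dysmorphic triangles) and 0.02 MPa/mm between adjacent levels.
   Nodes are capped at their nominal radius.
4. Convergence: max pressure imbalance ≤ 1e-6 MPa (intermediate releases
   are solved 100× looser; the final release to full tolerance).
   Tolerated penetration at convergence is ≤0.05 mm against a rigid wall.
5. Contacted anatomy triangles are displaced outward by contact pressure /
   tissue stiffness, capped at the tissue thickness (first-order wall
   compliance without volumetric meshing).

Tissue parameters are the published linear-elastic set: wall E = 2 MPa,
t = 2 mm; leaflets E = 0.6 MPa, t = 1.5 mm; calcium E = 4 MPa with a
0.6 MPa yield.  The solver is deterministic (fixed iteration order, no
randomness); increasing any tissue modulus can only decrease deployed
radii.

## Sealing analysis

For every skirt element: centroid, area (two triangles) and outward unit
normal are computed on the deformed 3D element; the first anatomy
intersection along the normal gives the distance and the region/material
attribution.  If no triangle lies within the ray length (15 mm), the
nearest-point distance is used and flagged; if even that fails the element
is UNRESOLVED and later folded into the nearest resolved region by angular
proximity (the fraction is reported and is 0 on the default cohort).
An element is apposed iff distance < 1 mm — strictly, so exactly 1 mm is
malapposed.  Areas are summed on the 3D elements; the published workflow
projects to 2D before measuring, but 3D summation avoids projection
distortion and is declared canonical here, with the unrolled
(θ·r_ref, z) map kept for visualization only.  The ascending aorta is
quantified but excluded from all totals and percentages, matching the
published table arithmetic (the three-region sums reproduce the printed
total malapposition within rounding).

The surrogate PVL grade thresholds (none/trace < 10%, mild < 25%,
moderate otherwise) are calibration defaults chosen so the two published
anchor cases (4.4% → grade 0, 20.9% → grade 1) classify correctly; they
are configuration, not measured values.

## Frame metrics

Cross-sections are taken at four device levels — ventricular end (0.02),
nadir (0.15), central coaptation (0.45), commissures (0.70 of frame
height; the exact clinical level definitions are not public, so the
fractions are configuration).  Each section polygon is measured as: dmax =
max pairwise vertex distance; dmin = minimum width of the convex hull
(rotating calipers); perimeter; shoelace area.  At 96 vertices all four
match circle closed forms to <0.2%.  Predicted-vs-observed comparison
(mean difference, SD, R² = squared Pearson correlation) uses synthetic
observations — predicted + constant bias + seeded noise — as a stand-in
for post-operative CT, which makes the comparison stage testable but says
nothing about real imaging accuracy.

## Statistics

* Pooled two-sample t-test, computable from printed group summaries
  (sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)).  The published methods text
  mentions a paired test, but the tables compare unequal-sized groups
  (26 vs 17) where pairing is impossible, and the pooled form reproduces
  the printed p-values (0.030/0.195/0.987) from the printed summaries to
  within half a unit of their last digit — that agreement is the
  justification for the pooled reading.
* Mann–Whitney U: exact enumeration when n₁+n₂ ≤ 20 without ties,
  tie-corrected normal approximation otherwise; the path taken is reported.
* Fisher's exact test, two-sided by the probability-ordering convention
  (sum of same-margin tables no more probable than the observed one),
  which reproduces the printed 0.376 and 1.000.
* Group summaries pool BAV0+BAV1 into a BAV column and compare BAV vs TAV;
  continuous rows use the t-test when both groups pass Shapiro–Wilk at
  α = 0.05 and Mann–Whitney otherwise (flagged), categorical rows use
  Fisher.  The source tables only footnote which rows used Mann–Whitney,
  so the normality gate is this package's explicit rule.
* Univariate screen: per-candidate simple-regression slope test, retaining
  p < 0.1 strictly.  Stepwise regression: forward entry at α = 0.05,
  backward removal at α = 0.10, iterated to a fixed point; candidates are
  standardized internally (scaling invariance), entry ties break by
  smallest p then column order, and near-perfectly collinear candidates
  (R² > 0.999 on current terms) are skipped.  Entry/stay thresholds are
  conventional defaults; only the 0.1 screening rule is stated by the
  source.

## What the synthetic cohort does and does not show

The generator encodes the anatomical hypothesis (absent/underdeveloped
interleaflet triangles in BAV) directly as deeper wall recesses, plus the
published covariate differences (higher calcium burden, lower sizing
index).  Passing the cohort-level tests therefore shows that the
*pipeline* — deployment, ray-cast classification, area bookkeeping, group
statistics — correctly propagates that anatomy into the published
direction of effect (higher interleaflet-triangle malapposition in BAV,
flagged at p < 0.05 at the default seed); it does not validate the
hypothesis against real patients, and absolute percentages are not
comparable to the clinical ones.  With 43 patients and the configured
effect size the group comparison is significant for most seeds but, as in
any finite sample, not guaranteed for every draw.

## Numerical and engineering choices

* Ray casting is vectorized Möller–Trumbore over all triangles per ray —
  exact, deterministic, and fast at ≤10⁴ triangles; it doubles as its own
  brute-force reference and is cross-checked in the tests against an
  independently formulated plane-intersection/edge-sign oracle (1e-9
  agreement).  Closest-point fallback uses a plane/segment-distance
  decomposition per triangle.
* Mesh I/O goes through trimesh (STL binary/ASCII, PLY); region/material
  labels travel in a JSON sidecar because STL/PLY carry no attribute
  channels.  Spatial-index-accelerated trimesh queries are not used.
* Degenerate inputs are rejected with explicit errors: non-monotone frame
  profiles, crimp targets at or above the minimal nominal diameter,
  off-leaflet calcium, empty record lists, z-planes outside a mesh,
  infeasible covariate bounds.
* Problem sizes (96×60 anatomy, 24×32 frame, 43 patients, 1000/200
  calibration replicates) keep the full pipeline around one minute on a
  single CPU.

## Known limitations

* No leaflet motion, hemodynamics, or regurgitant-volume estimation: the
  malapposition percentage is a geometric surrogate for paravalvular leak.
* No axial migration or friction mechanics; depth is prescribed.
* The frame is a generic lattice, not the clinical strut geometry; radial
  forces are in arbitrary but consistent units of the configured stiffness.
* Anatomy deformation is a local radial displacement, not a volumetric
  tissue model; stress fields (e.g. conduction-system pressure) are out of
  scope.
* The "observed" frames in the comparison stage are synthetic
  perturbations; R² there measures pipeline plumbing, not imaging
  validation.
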