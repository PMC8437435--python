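# Methods

This note documents the models, statistics and numerical choices behind
`jmpkit`, what the synthetic scenes do and do not emulate, and the known
limitations of each stage.

## 1. Membrane dynamics maps (2D)

**Statistic.** For a membrane-label movie I(t, y, x) the dynamics map is
the per-pixel temporal coefficient of variation

    CoV(y, x) = σ_t[I] / μ_t[I],

with the *population* standard deviation (divide by T): the map is a
descriptive statistic, not an estimator with degrees-of-freedom
correction.  Pixels whose temporal mean falls at or below 10⁻⁶ of the
stack's global mean are undefined (NaN), as are pixels touched by
registration borders.

**Corrections.** Intensity fluctuations also arise from photobleaching
and stage drift, so both are removed first:

* *Bleaching* — frame-mean normalization: each frame is divided by its
  mean over a fixed foreground mask (Otsu on the temporal-mean image) and
  rescaled to the frame-0 mean.  This is parameter-free and exact for any
  per-frame multiplicative decay, without committing to a mono-exponential
  model.
* *Drift* — translation-only phase correlation of every frame against
  frame 0 (subpixel by upsampled cross-correlation, factor 10).  Frame 0
  is the reference because the monolayer's geometry is defined at
  experiment start; pixels shifted in from outside the field become NaN so
  borders never contaminate the statistics.  Both the reference-frame
  choice and the border treatment are design decisions of this package.

**Junction band.** Analysis is restricted to pixels within 3 µm
(Euclidean, physical units) of the junction skeleton; the junction mask is
a primary input (skeletonized internally) rather than being segmented from
a marker channel, to keep hidden segmentation variance out of the
statistic.  The scalar read-out is the mean over defined band pixels,
optionally divided by a reference condition's summary — normalization is
applied at the summary level, per image, not per pixel map.

**Ratios and line scans.** Before/after-inhibitor and cell-A/cell-B
asymmetry ratios are ratios of band-summary means over caller-supplied
ROIs.  Junction line scans average a 30-pixel-wide line perpendicular to
the junction (z-stacks are summed first) and report the profile plus the
cumulative signal normalized by sampled area.

## 2. 3D protrusion detection and morphometry

**Valid mask.** Deskewing oblique light-sheet acquisitions pads each z
slice with zeros.  The usable region is the union of non-zero voxels over
the first 50 frames, with per-slice 2D hole filling.

**Segmentation.** Otsu threshold computed from intensities inside the
valid mask only; connected components smaller than 0.1% of the mask voxel
count are discarded, and components whose convex-hull volume exceeds 50%
of the mask volume are discarded as whole-frame noise bursts (the frame
then yields an empty segmentation and a logged skip).  Hulls are computed
on component border voxels.

**Surfacing and smoothing.** Marching cubes at the anisotropic physical
voxel size (vertices in µm, axis order z, y, x), degenerate faces removed;
then four iterations of mean smoothing in which every vertex moves to the
mean of itself and its 1-ring.  Interior flat regions are fixed points;
open-boundary rings shrink slightly, which is irrelevant because flat
boundary vertices carry zero variation.

**Surface variation.** For each vertex v with unit normal n̂, collect the
graph neighborhood {u : d_edges(u, v) ≤ 20} by BFS.  Project the
neighbors onto n̂: heights h_u = (p_u − p_v)·n̂ and in-plane radii
r_u = |(p_u − p_v) − h_u n̂|.  The statistic is the volume of the minimal
normal-aligned enclosing cylinder,

    V(v) = π · (max r_u)² · (max h_u − min h_u),

in µm³ on the physical-unit mesh.  The neighborhood is graph distance (not
geodesic length) because the 1-ring is defined by mesh edges; boundary
vertices with truncated neighborhoods are computed from the available
neighbors and flagged.  The inner loop (BFS plus running extrema) is a
numba kernel; a brute-force NumPy/networkx implementation in the test
suite is the independent oracle.

**Labeling.** Vertices with V > 3.5 are protrusive.  The threshold is kept
at 3.5 for fidelity and is configurable; its units follow whatever units
the mesh carries (µm³ here).  Nuclear regions — where the thin perinuclear
membrane defeats the statistic — are excluded by a manually drawn 2D
polygon projected through z.  The label set is refined by mesh-morphology:
opening with a 1-neighborhood (erosion then dilation on the vertex graph),
closing with a 5-neighborhood, then filling enclosed unlabeled holes
(unlabeled components that do not touch the mesh boundary; on a closed
mesh the largest unlabeled component is treated as the outside).  All
three refinement operators are monotone, so raising the threshold never
increases the labeled set.

**Region extraction.** Faces whose three vertices are labeled are grouped
by shared-edge connectivity; regions under 10 faces are dropped (fan caps
on 1–2-face fragments are meaningless).  Each boundary loop is capped by a
fan to the loop centroid, preserving orientation; volume is the
divergence-theorem volume of the watertight result (absolute value) and
the base area is the total cap area.  Non-manifold edges are repaired by
dropping their faces, with a log message.

**Known limitation — base-area spillover.**  The cylinder statistic is
nonlocal with support equal to the neighborhood reach (≈ 20 edge lengths,
~4 µm at 0.2 µm voxels).  Every *flat* vertex whose neighborhood reaches a
protrusion inherits a large height extent, so labels spill roughly one
neighborhood radius beyond the protrusion rim regardless of the threshold
(the variation value 0.15 µm outside the rim differs from the rim value by
<2%).  The spill annulus is flat, so region *volumes* are essentially
unaffected (within ~1% for hemispheres of r = 3–8 µm), but cap *base
areas* are inflated severalfold relative to the geometric footprint πr².
This is a property of the statistic itself — any labeling built on it
inherits the same spill — and base areas reported by this pipeline (and
by the approach it follows) should be read as "footprint of the detected
high-variation region", not as the geometric footprint of the protrusion.
The measurement machinery is exact: with exact geometric labels, capped
volumes and base areas agree with ⅔πr³ and πr² to a few percent.

**Scale equivariance.** Scaling coordinates by k scales V(v) and region
volumes by k³ exactly (verified at k = 2 to 10⁻⁶ relative).

## 3. Stain coverage

Per-vertex stain values are the mean of the 2×2×2 voxel block enclosing
the vertex position (voxel centers at integer index × voxel size, the
marching-cubes convention); vertices outside the stain volume are flagged.
Stained = strictly above an Otsu threshold over the per-vertex values.

Edge distances are multi-source Dijkstra shortest paths along mesh edges
(weights = physical edge lengths) from the uncapped region's boundary
vertices, implemented with a zero-weight super-source; this graph geodesic
overestimates the true polyhedral geodesic by at most the local
metrication factor of the triangulation (a few percent on the meshes
used).

The coverage profile bins stained vertices by edge distance into 20 bins
for the reported histogram/ECDF, but the percentile distances d50/d75/d90
are the *direct empirical quantiles* of the stained-vertex distances,
normalized by the region's maximum edge distance.  A bin-upper-edge
readout was considered and rejected: at 20 bins it quantizes the statistic
by 0.05 — coarser than the statistic's own resolution — and the uniform-
disk reference value d75 = 0.5 sits exactly on a bin edge, making the
readout unstable to any perturbation.  Quantiles are equally deterministic
and monotone (d50 ≤ d75 ≤ d90 always; all values in [0, 1]).  The
histogram is over stained-vertex *counts*, not stain-intensity mass.
Per-dataset aggregation averages normalized percentile distances over
frames.

Analytic reference: for uniform areal stain on a flat disk,
d_p = 1 − √(1 − p), i.e. 0.293 / 0.500 / 0.684; the implementation
reproduces these within 0.02 at ≥2000 vertices, with the residual
dominated by triangulation metrication.

## 4. FRET ratio processing

Per frame: background (mean of a cell-free ROI) is subtracted from each
channel; the acceptor is registered onto the donor by translation-only
phase correlation; both channels are smoothed with a 3×3 uniform mean —
the conventional "smooth" of the software tradition this follows.
Smoothing precedes bleed-through subtraction; since both operations are
linear the order only matters at object borders, and the chosen order is
logged.  The ratio is

    R = (acceptor − α · donor) / donor,   α = 0.62,

undefined where the donor is at or below 1% of its foreground (Otsu) mean;
negative corrected-acceptor pixels are clipped to undefined and counted.
R is invariant under common gain, and a generator round trip at zero noise
recovers the true ratio to 10⁻¹⁰.

"Approximately cover 50% of the junction" is operationalized as the median
ratio over the 1 µm junction band (deterministic and scale-free), with
median-valued ties promoted in raster order so discrete-valued bands still
split at 50%.  Diapedesis sites are scored high/low by the nearest band
pixel.  JMP ROIs (drawn on the acceptor channel) are compared against the
3 µm junction band mean of the same cell, one row per ROI.

## 5. TEM event classification

Tracks are supplied as tables (one position per 5 s frame); tracking
itself is out of scope because the source data were tracked manually.
Rules, with boundary conventions:

* *Crawling*: interval displacement strictly below 10 µm per 5 s frame
  (exactly 10 µm ⇒ rolling).  Time gaps larger than 1.5× the nominal
  interval are skipped and flagged.
* *First junction contact*: first crawling-phase frame within 1 px of the
  junction mask (Euclidean distance transform).  For tracks with known
  positional noise the caller passes a tolerance of ≈3σ in pixels; and a
  diapedesis-annotated track that never passes the tolerance falls back to
  its nearest crawling-phase approach (diapedesis implies the junction was
  touched; the strict rule would otherwise discard the event).  Tracks
  without diapedesis annotation that never touch a junction get undefined
  flags.
* *first_junction*: the diapedesis site lies on the same connected
  component (8-connectivity) of the junction mask as the first contact.
* *lateral*: along-junction geodesic distance (minimum-cost path on
  junction pixels, physical units) from contact to site exceeds 10 µm —
  along the junction, not straight-line, because the cells crawl along the
  junction.  *immediate* = first_junction and not lateral.
* *turn*: the cell label under the neutrophil the frame before diapedesis
  differs from the arrival-side label (the label one frame before first
  contact).
* *at JMP*: the mean of the pre-arrival dynamics map over a 1 µm disk at
  the site strictly exceeds 2× the map's mean over defined pixels.  The
  map must be computed from frames before the neutrophil arrived so its
  own membrane disturbance is excluded.  The call is invariant under
  global map scaling.
* *Relative MD increase*: (mean₁ − mean₂)/mean₂ with region 1 a disk of
  default radius 5 µm at the site (the region's size is not fixed by the
  source convention; 5 µm is a neutrophil-scale choice, configurable) and
  region 2 a 10 µm region at the first contact.
* *Change after TEM*: dynamics-map summaries over the site disk from the
  frames before arrival (v₁) and the 30 frames after the neutrophil left
  (v₂); reported as (v₂ − v₁)/v₁, with v₂/v₁ available via
  `mode="ratio"` since figure-level conventions for this quantity are
  ambiguous.

## 6. Synthetic scenes: what they emulate, and what they do not

* **Monolayer movies** — Voronoi cells (convex, like a confluent
  monolayer's first-order geometry), bright junction bands (membrane
  accumulates at cell–cell contacts: cytoplasm 50, junction 150 counts),
  and circular dynamic patches on junctions whose intensity is modulated
  per frame by 1 + a·s_t with s_t ~ U(−1, 1) — a high-CoV stand-in for JMP
  flickering.  Bleaching is per-frame multiplicative decay, drift a rigid
  per-frame translation, noise additive Gaussian clipped at zero (the
  simplest model sufficient for CoV and Otsu behavior).  Defaults: 40
  frames at 0.18 µm pixels, noise σ = 2 counts, patches of radius 2.5 µm
  and amplitude 0.5.  Not emulated: PSF blur, shot-noise statistics,
  junction remodeling, cell motion.
* **Membrane volumes** — a 3-voxel-thick sheet (thin enough to surface as
  two separate open sheets, thick enough to segment) spanning the full
  x-y extent, so marching cubes produces no side walls whose box edges
  would masquerade as high-variation regions.  Protrusions are *solid*
  hemispheres or half-cylinder ridges fused onto the sheet: the outer
  surface is then a single closed cap with closed-form volume and base
  area, which is what the morphometry oracles need; a hollow shell would
  mesh as two nested surfaces and break the one-region-per-protrusion
  ground truth.  Both protrusion kinds have closed forms (hemisphere:
  ⅔πr³, πr²; ridge: ½πr²L, 2rL).  Deskew padding is emulated as a
  z-dependent zero wedge; the deskew/deconvolution algorithms themselves
  are out of scope.  Default voxels (0.211, 0.104, 0.104) µm, membrane 100
  versus background 10 counts.
* **Stain channels** — intensity on a one-voxel shell around each
  protrusion surface, either within the outer 10% of the rim-to-apex arc
  (edge), constant (uniform), or Gaussian-weighted in polar angle peaking
  at the apex (center).  Real stains are neither shell-confined nor
  noise-free rings; these are limiting cases the coverage statistic must
  order correctly.
* **FRET pairs** — acceptor = (ratio + α)·signal + background + noise by
  construction, over a smooth random blob field; no spectral complexity
  beyond the single bleed-through coefficient.
* **Tracks** — a rolling approach (12 µm/frame, confined to the arrival
  cell so ambiguous junction crossings cannot occur during rolling), a
  crawling run (2.5 µm/frame) ending exactly at the contact point, and an
  event-specific ending.  Lateral walks follow the junction restricted to
  pixels bordering the arrival cell — an unrestricted walk can cross a
  Voronoi triple point onto another cell pair's junction, which would
  genuinely turn the event into a "turn" and falsify the constructed
  flags.  The frame before diapedesis is guaranteed to carry the intended
  cell label.  Truth flags are set by construction, never by running the
  classifier.

Passing tests on these scenes demonstrate that each rule and statistic
recovers known ground truth under the stated noise models; they do not
demonstrate robustness to PSF blur, segmentation errors on dim membranes,
junction remodeling during acquisition, or manual-tracking biases in real
movies.

## 7. Problem sizes and tolerances

The test suite and acceptance script run the 3D pipeline at 256×256×64
voxels (0.2 µm isotropic; three hemispheres r = 3, 5, 8 µm, noise σ = 2),
a size at which marching cubes yields ~1.5·10⁵ vertices and the numba
variation kernel completes in seconds.  Registration checks use 256²
movies with drifts up to ±5 px; FRET round trips use 128² maps; TEM
recovery uses 50 events on a 6-cell monolayer.  Key tolerances: CoV
against the two-loop reference 10⁻¹²; sphere volume 3%; hemisphere
volumes 10% (observed <1%); disk coverage percentiles 0.03; noise-free
FRET recovery 10⁻¹⁰ and 2%-noise MAE < 0.02; TEM flags 100% noise-free
and ≥95% at 0.5 µm positional noise; scale equivariance 10⁻⁶ relative.
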