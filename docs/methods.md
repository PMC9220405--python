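# Methods

## Problem

`hiveweave` generates 3D-printable scaffolds for mycelium-bound beehives:
porous lattice bodies that a fungal culture can colonise, shaped around the
habitat requirements of a honeybee colony (a 25–40 L warm, dark nest cavity;
an entrance; a load-bearing, insulating enclosure) and the constraints of
large-format extrusion printing (bed diameter, safe module height, continuous
paste/filament deposition, clay drying shrinkage).

All internal geometry is in millimetres; litres and centimetres appear only
at the configuration and reporting boundary. Geometric predicates use an
absolute snap tolerance of 1e-6 mm.

## Continuous hexagonal weaving

The fabrication primitive is a single closed extrusion polyline per layer
that traverses the vertices ("control points") of every hexagonal cell of a
lattice patch. We realize it as a Hierholzer Eulerian-circuit walk on the
cell-edge multigraph in which each cell contributes its six boundary edges;
an edge shared by two cells therefore appears with multiplicity two. Every
cell contributes an even degree (2) to each of its six vertices, so all
multigraph degrees are even and a closed Eulerian circuit exists on any
connected grid — uninterrupted extrusion is guaranteed by graph theory, not
by heuristic path search. Determinism: the walk starts at the
lexicographically smallest vertex of the start cell (default: the cell with
the smallest axial id) and breaks ties toward the lowest neighbor key, so a
given grid always yields a byte-identical toolpath.

Weave features:

* **Linear bonding** — the doubled traversal of each interior (shared) cell
  edge. With a nonzero bead width the two passes are offset a quarter bead
  to either side and cut the corner near hexagon vertices, so the runs are
  visibly parallel rather than coincident.
* **Point bonding** — transversal self-crossings of the path, which arise at
  hexagon vertices between the corner-cut connectors of different passes.
  The exact over/under crossing order of the physical threads is not modelled;
  the planar path crossing is the feature we count.
* **Drape zones** (opt-in, off by default for printability) — straight
  doubled chords spanning missing lattice cells that are enclosed holes
  (at least four present neighbors). Doubling the chord keeps every vertex
  degree even, so the single-stroke property survives; the chord is extruded
  in free air.

Hexagons are pointy-top with axial (q, r) coordinates and circumradius `s`
(lattice pitch `s*sqrt(3)`); a global rotation parameter serves layouts that
need the other orientation. Cell membership in a clipped region is decided by
the cell **center** (boundary ties count as inside), which keeps narrow weave
zones between tight offsets populated.

## Variable-offset (VO) generation

A closed contour is offset inward by a schedule of distances, each entry
typed `wall` (printed perimeter), `weave` (hexagonal weave fill of the
annulus between consecutive offsets) or `channel` (cells reserved as open
vertical tubes for "infill-feed" inoculation with mycelium-bearing
substrate). The hex lattice origin is shared across layers, and the channel
footprint is fixed once from the base contour, so channel cells stack into
vertical tubes along their whole z-extent. Channel cell size is raised to
at least `channel_diameter/sqrt(3)` so the across-flats width of the
hexagonal tube matches the configured channel diameter.

A full hive adds, from bottom to top: the nest body (contour = cavity
profile radius + total wall schedule), an entrance bore with optional
landing-platform protrusion just above the cavity floor, and a fully woven
roof disc over the top `roof_thickness/layer_height` layers (coarser weave
by `roof_weave_scale`, the thick moisture-buffering zone). The cavity
profile is solved in closed form from the target volume (cylinder:
`r = sqrt(V/(pi h))`; tapered: frustum volume inverted for the base radius).
Cavity and enclosure meshes are polygonal prisms whose cross-section area is
corrected to the exact circle area, so the reported cavity volume equals the
target analytically, not just within mesh tolerance. Identical layers share
one computed slice pattern (the body of a cylindrical hive is a stack of
identical slices), which keeps full-hive generation near-interactive.

The "self-feed" inoculation preset (liquid culture poured over a
nutritionally printable scaffold) halves the weave cell size relative to the
infill-feed presets.

## Iterative-subtraction (IS) generation

Material is distributed over a voxel domain by density-based topology
optimization (SIMP):

* modified-SIMP interpolation `E(rho) = Emin + rho^p (E0 - Emin)` with
  `E0 = 1`, `Emin = 1e-9`, `nu = 0.3`, default `p = 3`;
* 4-node bilinear quads (2D test mode) / 8-node trilinear hexahedra (3D),
  unit elements integrated with 2-point Gauss quadrature — the density field
  is invariant to uniform element scaling and to load magnitude, and the
  voxel edge length carries the physical scale;
* cone-kernel sensitivity filtering (default radius 1.5 voxel units;
  a mass-conserving density-filter variant is selectable);
* optimality-criteria update with move limit 0.2 and bisection on the
  Lagrange multiplier to relative width 1e-10, so the volume-fraction
  constraint holds to well under 1e-3 at every iterate.

Loads are configured in kgf (colonies are weighed in kilograms) and
converted to newtons at 9.81; each load spreads equally over its voxel's
corner nodes, supports fix all corner nodes of their voxels. A fixed
iteration budget (default 15 in 3D pipelines, 30 for 2D benchmarks) keeps
runs deterministic.

Attractors superpose density gradients after optimization:
`rho' = clamp(rho + strength * max(0, 1 - d/falloff), 0, 1)` with Euclidean
point or segment distance — plain compliance optimization yields near-uniform
porosity, and the attractors are the designed density differentiation.

Thresholded voxels (default tau = 0.5) are replaced by hex cells via the
bijective odd-r offset-to-axial map `(i, j) -> (i - (j - (j&1))//2, j)`,
so per-layer cell counts equal above-threshold voxel counts exactly; the
default cell size makes the lattice pitch equal the voxel edge. The nest is
carved **after** thresholding (the structural field is not re-optimized
around the cavity): the `enclosed` variant removes cells inside a centered
cylinder of the spec volume, the `open` variant carves a recess that pierces
the top boundary. Layers that split into several components after carving
are woven per component and reported.

## Design-space exploration

The explorer evolves named parameter vectors (cavity radius/height, weave
cell size, zone widths) inside a bounded box: tournament selection (size 2),
uniform crossover (rate 0.8), Gaussian mutation (sigma = 5% of each range,
rate 0.1), elitism, clipping to bounds. Each generation the population is
clustered by seeded k-means in normalized genome space and cluster medoids
are surfaced as representatives. Batch mode minimizes a weighted objective
sum (toolpath length as the material/time proxy, cavity-volume error,
channel capacity, constraint penalty); interactive mode accepts a list of
preferred representative indices and scores genomes by proximity to them.
Clustering is performed in genome space (objective-space clustering would
group visually dissimilar designs). Objective evaluation generates one
representative slice per genome and scales by the layer count, memoized on
the rounded genome; infeasible genomes receive finite penalties, never
exceptions. All randomness flows through a single `numpy` generator seeded
per run, so fixed seeds reproduce every draw byte for byte.

## Fabrication

* **Ring modules**: the scaffold is split into `ceil(height/limit)` uniform
  modules with half-open z-ranges `[z0, z1)` snapped to layer boundaries;
  module height and lateral bounding-circle diameter are checked against the
  machine profile (defaults 15 cm / 40 cm).
* **Shrinkage**: clay shrinkage is a **linear** per-axis factor (the
  convention in which clay bodies are specified); compensation pre-scales
  each axis by `1/(1-factor)` so that shrinking the printed part reproduces
  the design. The measured clay hive numbers (39 L printed, ~30 L fired) are
  consistent with about 8.3% linear / 23% volumetric, not with 20% under
  either reading; both interpretations are expressible through the per-axis
  configuration, and the shipped clay config uses the nominal 0.2 linear
  value it was quoted at.
* **G-code**: minimal Marlin-compatible subset, absolute extrusion (M82,
  G92 E0). Within a layer every move extrudes; the approach move per
  toolpath is the only travel. The E-register advances by
  `length * bead_width * layer_height / (pi (d_f/2)^2)` on filament
  machines and volumetrically (scale 1, mm^3) in paste mode. Writer
  precision is 0.1 mm; re-parsing emitted G-code recovers the source
  vertices to that precision.

## Validation

`validate_design` measures cavity volume (watertight mesh required),
entrance diameter, channel verticality, module limits and the configured
load-case total, and emits a JSON report with one entry per constraint.
The default volume band is the 25–40 L feral-colony preference; the
GrowLay Hive-2 reconstruction deliberately exceeds it (45 L) and overrides
the band in its config. Entrance bounds have no default: validation fails
loudly if they are not configured. Volume bounds are inclusive.

## Synthetic data and what tests show

No external datasets exist; every input is generated: parametric contours
(circles, rounded rectangles, seeded star polygons), box voxel domains,
cantilever and colony-floor load cases (the colony-floor default totals
80 kgf — the design load of a full colony with stores), and seeded
random-walk connected hex grids for weave stress tests. The shipped hive
configs reproduce the documented quantities of the two built hives (45 L
and 39 L nest volumes, 40 cm/15 cm machine limits); their wall schedules,
heights and cell sizes are reconstructions — geometric plausibility, not
measurement. Passing tests therefore demonstrate the correctness of the
geometry, traversal and optimization machinery, not the biological
performance of any hive: mycelium colonisation, moisture/thermal behaviour
and colony acceptance are outside the model.

## Problem sizes and numerical notes

* Hive generation: 128-segment contours, 2 mm layers (a 50 cm hive is ~280
  layers, generated in ~1 s thanks to slice caching).
* SIMP benchmarks: 8x5 two-dimensional cantilever for the reference-
  implementation comparison (30 iterations); the mesh-independence check
  runs 64x40 vs 128x80 with an edge-distributed load — at coarser sizes the
  bending response of bilinear quads is dominated by discretization error
  (shear locking), which is a property of the element, not of the optimizer.
* 3D IS runs default to 16x16x12 voxels, 15 iterations (about 11k dofs per
  solve with a direct sparse factorization).
* Explorer property runs use population 24 for 20 generations; objective
  memoization makes repeated-genome evaluations free.
* The OC bisection terminates at relative width 1e-10; the series-bar
  closed form shows the update can oscillate within the move limit around
  a symmetric optimum — standard OC behaviour; production runs rely on the
  filter to damp it.

## Known limitations

* The weave models a planar continuous-extrusion pattern; true over-under
  interlacing of separate threads is out of scope.
* The entrance bore is represented as explicit bore geometry and validated
  dimensionally; it is not boolean-subtracted from the enclosure mesh.
* Offsets use round joins; mitre behaviour at sharp corners is not
  observable at bead widths >= 1 mm and is not configurable.
* Print-time and filament-mass figures are nominal estimates for the
  explorer objective only; they are hardware-dependent and not validated.
* Topology optimization is compliance-only (no stress constraints, dynamics
  or thermal loads) and is not a code-compliant structural verification.
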