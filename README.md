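# hiveweave

Generative design and continuous-extrusion fabrication of porous mycelial
beehive scaffolds.

Mycelium-bound composites can give honeybee colonies what modern hives lack:
thick, breathing, thermally buffered nest enclosures like the tree cavities
feral colonies prefer (25–40 L). Growing such a hive requires a 3D-printed
*stay-in scaffold*: a porous lattice the fungus colonises and bonds.
`hiveweave` is the computational half of that workflow, for designers and
researchers in biofabrication: it generates scaffold morphologies, draws
their toolpaths, explores the design space, and slices the result into
printable instructions.

## What it computes

* **Continuous hexagonal weaving** — one closed extrusion polyline per layer
  traversing every cell of a hexagonal lattice patch. Interior cell edges are
  doubled, which makes every vertex degree of the cell-edge multigraph even,
  so a Hierholzer walk always yields a single uninterrupted stroke (no travel
  moves — essential for paste extrusion). Doubled runs are the *linear
  bonding* features, path self-crossings the *point bonding*, optional chords
  across missing cells the *drape zones*.
* **Variable-offset (VO) method** — a contour is offset inward by a schedule
  of distances `(d_i, role_i)` with roles `wall | weave | channel`; weave
  annuli are filled with the hexagonal weave, channel zones reserve vertical
  tubular hex cells for mycelium inoculation. Stacked slices plus a
  closed-form cavity profile (`r = sqrt(V / (pi h))` for a cylinder) give a
  full hive: nest cavity, woven roof, entrance, landing platform.
* **Iterative-subtraction (IS) method** — SIMP topology optimization
  (`E(rho) = Emin + rho^p (E0 - Emin)`, optimality-criteria update with the
  volume fraction held exact by bisection, sensitivity filtering) distributes
  density over a voxel domain under colony load cases; point/line attractors
  superpose density gradients; thresholded voxels become hex cells and are
  woven; a nest cavity is carved (enclosed or open variant).
* **Cluster-oriented genetic algorithm** — seeded evolution over the named
  design parameters with k-means clustering in genome space; cluster medoids
  are surfaced as representative designs, balancing toolpath length
  (material/time) against habitat objectives.
* **Fabrication** — splitting into ring modules (default limits: 40 cm bed,
  15 cm module height), linear clay-shrinkage compensation
  (`scale = 1/(1-factor)` per axis), continuous-extrusion G-code with a
  volumetric E-register, and material estimates.
* **Validation** — cavity volume against the 25–40 L preference band,
  entrance size, channel verticality, machine limits, 80 kgf design load.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Generate the demo hive (a 30 L nest) and validate it:

```sh
hiveweave generate-vo --config src/hiveweave/examples/demo.yaml --out-dir out/demo
```

prints

```json
{
  "cavity_volume_l": 30.0,
  "layers": 280,
  "toolpaths": 810,
  "channels": 60,
  "layer_height_mm": 2.0,
  "total_height_mm": 560.0
}
```

— the cavity volume hits the 30 L target (the profile is solved in closed
form and the mesh cross-section is area-corrected), the hive is 280 printed
layers of 2 mm, and 60 hexagonal channel cells run vertically through the
wall for inoculation. `out/demo/` holds the cavity and enclosure STL meshes,
one plain-text polyline per toolpath, and the design report.

```sh
hiveweave validate --config src/hiveweave/examples/demo.yaml
```

reports every benchmark with its measured value, e.g. cavity volume 30.0 L
in [25, 40] L → pass, entrance 60 mm in [40, 80] mm → pass, channels
vertical → pass, module height 14 cm <= 15 cm → pass, design load 80 kgf →
pass.

The same workflow drives the two documented hive reconstructions
(`growlay_hive2.yaml`, 45 L nest; `clay_hive.yaml`, 39 L as printed on a
40 cm bed), the IS pipeline (`hiveweave generate-is`), the explorer
(`hiveweave explore`) and G-code emission (`hiveweave gcode`).

As a library:

```python
from hiveweave import radial_grid, weave, continuity_check

path = weave(radial_grid(rings=2, s=6.0))   # 19 cells, one stroke
assert continuity_check(path).continuous     # no travel moves, no gaps
```

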