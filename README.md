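# dotmap

Display two or more scalar datasets on a single 3D cardiac chamber model by
combining a colour-shaded mesh with a density-stippled dot overlay. One
dataset is painted on the surface through a colormap; additional datasets are
drawn as randomly placed dots whose local density is proportional to the
underlying values, so the colour layer stays visible "through" the dots.

The dot counts follow a distance-corrected, Poisson-sampled weighting of
per-element scalar values:

- each triangle/tetrahedron gets a weight `lam = V * S * D^2 / D'^2`
  (element measure x normalized scalar x squared ratio of reference to
  current viewpoint distance), adjusted by brightness/contrast controls
  `lam_adj = b * lam^c`;
- the dot count per element is Poisson(`lam_adj`), truncated at the cap
  `N = ceil(q * V)`;
- each dot is placed uniformly inside its source simplex (square-root
  barycentric sampling for triangles, two-stage folding for tetrahedra).

Under a scaled orthographic camera the `D^2/D'^2` correction makes the
expected screen dot density invariant under zoom.

## Layout

| module | role |
| --- | --- |
| `dotmap.mesh_core` | triangle/tet meshes, element measures, vertex-to-element conversion, VTK legacy ASCII / PLY / OFF I/O, sidecar field CSVs |
| `dotmap.dot_sampler` | weights, capped Poisson counts, uniform simplex sampling, the full dot-cloud pipeline |
| `dotmap.scene` | view state, dot elevation along normals, deterministic software renderer (PNG), zoom density sweep |
| `dotmap.fixtures` | synthetic geometries: disc gradient, square scar, icosphere shells, volumetric wedge, activation/voltage field pairs |
| `dotmap.density_analysis` | machine analogues of the perception tasks (gradient axis, focal source), uniformity bench utilities |
| `dotmap.cli` | the `dotmap` command |

## CLI

```sh
# synthetic fixtures (VTK mesh + per-element field CSVs)
dotmap make-fixture --kind disc_gradient --params '{"resolution": 16}' --seed 1 --out disc
dotmap make-fixture --kind shell_pair --seed 2 --out shells

# render colour + dot layers to PNG (deterministic for a fixed seed)
dotmap render --mesh disc.vtk --color-field S --dot-field S --b 2000 --seed 5 --out disc.png
dotmap render --mesh shells_inner.vtk --mesh2 shells_outer.vtk \
    --color-field voltage --dot-field voltage --offset 1.0 --window 0,3 \
    --seed 9 --out shells.png

# screen dot density vs zoom level
dotmap density-sweep --mesh disc.vtk --dot-field S --zooms 0.5,1,2,4 \
    --q inf --b 20000 --reps 10 --seed 0 --out sweep.csv

# raw dot cloud as CSV or PLY
dotmap export-dots --mesh disc.vtk --dot-field S --b 500 --seed 3 --out dots.csv

# estimator battery on seeded synthetic tasks
dotmap perception-bench --trials 10 --dots 10000 --seed 0 --out bench.csv
```

All flags mirror keys of an optional JSON config (`--config`); explicit flags
win.

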