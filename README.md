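# fascitrace

Muscle fascicle tractography from Laplacian vector fields on simplicial
meshes.

Skeletal-muscle fascicles run from the origin attachment to the insertion
attachment without crossing, branching, or reversing. `fascitrace` encodes
this behavior as a harmonic (rotation- and divergence-free) vector field:
it solves the Laplace equation on a 2D triangle or 3D tetrahedral muscle
mesh with Neumann flux boundary conditions (uniform inflow on one
attachment, balanced outflow on the other, zero flux on the muscle belly),
traces fascicle tracts element-by-element through the conservative face-flux
field in barycentric coordinates, and quantifies fascicle length and
pennation angle.

## Components

| module | role |
| --- | --- |
| `fascitrace.mesh_core` | simplicial mesh model, Gmsh MSH (v2.2/v4.1) reader, legacy-VTK writers, patch tagging |
| `fascitrace.laplace_fv` | cell-centered finite-volume Laplace solver with Neumann flux BCs, deferred non-orthogonality correction, conservative face fluxes, per-element orientation vectors |
| `fascitrace.tracer` | flux-consistent barycentric streamline tracing with time-of-flight exit selection |
| `fascitrace.metrics` | spline smoothing + resampling to 100 equidistant points, fascicle length, pennation angle, summary tables |
| `fascitrace.synth_geometry` | deterministic synthetic test geometries (strip, fan, annulus sector, box), closed-form field oracles, random simplex fixtures |
| `fascitrace.cli` | `fascitrace run / demo / check` commands and pipeline orchestration |

## CLI

Run a canonical synthetic demo (writes mesh+field VTK, tract polylines,
metrics CSV, a JSON run report and — for 2D shapes — a plot):

```sh
fascitrace demo box3d --output-dir out_box
fascitrace demo annulus_sector2d --h 0.05 --output-dir out_annulus
```

Run a full pipeline from a YAML configuration (CLI flags override):

```sh
fascitrace run -c config.yaml --per-face 2
```

Minimal configuration for a Gmsh mesh:

```yaml
mesh_path: muscle.msh
patch_map: {prox: origin, dist: insertion, side: belly}
total_flux: 1.0
seed_patch: insertion        # seeds on the distal attachment, traced upstream
per_face: 1
n_points: 100
output_dir: out_muscle
```

Validate a mesh and its boundary conditions without solving:

```sh
fascitrace check -c config.yaml
```

Exit codes: 0 success, 2 configuration error, 3 numeric failure.

## Conventions

* Coordinates in mm; all indices 0-based (1-based MSH indices are converted
  on read).
* Faces are identified by their sorted node tuple; the adjacent element with
  the lower index owns the face and the stored integrated normal points
  outward from it.
* Boundary flux densities are positive outward; the belly density is exactly
  zero, which guarantees that no tract can terminate on the belly or inside
  the volume.
* The pure-Neumann nullspace is removed by pinning one element's potential
  (deterministic, configurable); the field is unique up to that constant.
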