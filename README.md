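# nuctract

Inverse traction-force inference from 2-D outlines of elastically deforming
cell nuclei.

Given two successive outlines of a nucleus (e.g. segmented from fluorescence
images of cells migrating through a micro-channel constriction), `nuctract`
finds the minimum-free-energy boundary correspondence between them by
Metropolis simulated annealing and computes the surface traction field that
would produce that deformation under two limiting mechanical models:

* **solid** — a homogeneous incompressible elastic solid (boundary
  displacement extrapolated linearly along radial spokes to zero at the
  centroid; nonlinear strain, incompressible Hooke law, z closed by
  ε_zz = −(ε_xx + ε_yy));
* **shell** — a thin (Love–Kirchhoff) elastic shell: only tangential surface
  strains, curvature-coupled tangential derivatives, traction parallel to
  the surface.

Everything upstream of the mechanics is included: Otsu thresholding and
outline extraction from TIFF/PNG images, contour CSV I/O, radial-spoke
ensemble averaging, translation-free pair alignment along the channel axis,
volume estimation from projected area × channel height, and a synthetic-data
module that generates channel/constriction shapes and deformation pairs with
exact ground truth so the whole pipeline is testable offline.

## CLI

```sh
nuctract simulate --kind ellipse --map-kind dilation --magnitude 0.1 \
    --out-initial i.csv --out-target t.csv
nuctract segment nucleus.tif -o outline.csv         # Otsu + outline trace
nuctract average stage_*.csv -o mean.csv            # radial-spoke average
nuctract align i.csv t.csv --out-initial ai.csv --out-target at.csv
nuctract anneal ai.csv at.csv -c config.yaml --out-mapping map.csv \
    --out-trace trace.csv
nuctract forces map.csv -c config.yaml -o traction.csv
nuctract volumes stages.yaml -o volumes.csv         # area x channel height
nuctract run -c config.yaml -o outdir/             # end-to-end
```

Configuration is YAML deep-merged over the documented defaults
(`nuctract.defaults.DEFAULTS`: E = 5 kPa, ν = 0.5, pixel 0.215 μm/px,
7 × 4.7 μm channel with a 2 × 3.4 × 20 μm constriction, 20 % initial
acceptance, move fraction 0.1, …). Every run writes the resolved effective
config next to its outputs; re-running with the same config and seed
reproduces every output byte-for-byte. A minimal `run` config:

```yaml
seed: 1
model: shell            # or solid
inputs:
  initial: i.csv        # a path, or a list of paths to average
  target: t.csv
plots:
  enabled: true         # quiver field + arclength profiles (250 Pa per μm)
```

Outputs: aligned contours, best point mapping, per-sweep energy trace,
surface-frame CSV (`s1_um, x_um, y_um, nx, ny, phi_rad, curvature_per_um`)
and the traction profile
(`s1_um, x_um, y_um, tx_Pa, ty_Pa, tmag_Pa, f_J_per_m3, model`), with
arclength s1 measured anticlockwise from the rearmost (minimum-x) point.

## Library sketch

| module | contents |
| --- | --- |
| `nuctract.contour` | `Contour` (simple, anticlockwise, μm) |
| `nuctract.contour_io` | Otsu threshold, outline extraction, CSV/TIFF/PNG I/O, volume |
| `nuctract.geometry` | centroid, area, angular remeshing, frames/curvature |
| `nuctract.ensemble` | spoke averaging, rear/front-weighted alignment |
| `nuctract.solid` / `nuctract.shell` | strain, stress, energy, traction per model |
| `nuctract.annealing` | equal-angle initial mapping, Metropolis annealing |
| `nuctract.synth` | synthetic shapes, deformation pairs, rasterization |
| `nuctract.pipeline` / `nuctract.cli` | orchestration, `nuctract` CLI |

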