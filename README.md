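# fibermatrix

Computational design loop for porous fibrous delivery matrices:

* **deposition_sim** — a voxel fiber-network simulator. Fibers are straight
  ribbons of voxels deposited sequentially onto a 3D grid; a depositing fiber
  drapes over the structure under an integer flexibility constraint (maximum
  vertical drop per lateral voxel step), taking the minimal admissible bottom
  surface, so rigid fibers bridge and flexible fibers conform.
* **structure_metrics** — surface/bulk porosity, pore-area distributions
  (8-connected void components, border pores included) and fiber-width
  morphometry (skeleton + Euclidean distance transform) on binary images and
  simulated structures, including SEM-style top views with a visibility depth.
* **image_analysis** — micrograph segmentation (global Otsu or fixed
  threshold, despeckling) and the image → metrics pathway with a
  stabilization report.
* **synthetic_data** — fiber populations over a configurable width range and
  phantom images with exactly known porosity/pore geometry, so the whole
  pipeline is testable without external micrographs.
* **design_explorer** — latin-hypercube / factorial / random sweeps over the
  simulator's input parameters, CART regression and decision trees over the
  results, and selection of the porosity / pore-uniformity optimum.
* **cli_report** — `fibermatrix` CLI wiring the stages with YAML configs,
  deterministic derived seeds and JSON run manifests.

## CLI

```sh
# one deposition simulation -> TIFF voxel stack, height map, top view
fibermatrix simulate --config sim.yaml --seed 3 --out run/

# micrograph analysis -> metrics JSON (+ optional binary mask)
fibermatrix analyze-image --in sem.tif --res 0.2 --method global-otsu --out metrics.json

# design-space sweep -> results.csv, trees, optimum report
fibermatrix explore --space space.yaml --base sim.yaml --n 200 --reps 5 --seed 7 --out sweep/

# Markdown + PNG report bundle from a finished sweep
fibermatrix report --sweep sweep/ --out sweep/report/
```

`sim.yaml` mirrors `SimConfig` (see `src/fibermatrix/configs/*.yaml` for
working examples); `space.yaml` mirrors `DesignSpace`. Every command writes
a `manifest.json` with a config echo, derived stage seeds and content hashes
of all outputs, on success and on failure.

## Conventions

* Solid = 1 / pore = 0 everywhere; grayscale renders make solid bright.
* Pore connectivity 8, solid connectivity 4; border-touching pores counted.
* Widths/thicknesses below one voxel clamp to one voxel — nano-scale
  populations should be simulated at finer `resolution_um_per_voxel`.
* Bulk porosity uses the covered-column thickness envelope by default; a
  full-domain variant is available via `bulk_porosity(..., convention="full")`.
* One master seed per run; all internal seeds derive from it
  (`design_explorer.derive_seed`), so any stage can be reproduced piecemeal.
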