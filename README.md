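# smlfm3d

Single-molecule light field microscopy (SMLFM) reconstructs the 3D
positions of individual fluorophores from the seven perspective views
formed by a hexagonal microlens array in the back focal plane of a
widefield microscope.  An emitter at defocus *z* appears displaced in the
view of the lenslet at normalized pupil position **u** by the parallax

    s(z, u) = z · tan θ · û ,      sin θ = |u| · NA / n ,

so grouping the per-view 2D localizations of one molecule and solving

    min over (x, y, z) of  Σ_k ‖ s_k − (x, y) − z·w_k ‖²

by least squares yields its 3D position; a fit is accepted when the RMS
per-view residual is below 200 nm and at least 4 views contribute.
Because a molecule does not need to be resolved in *every* view, emitters
that overlap laterally but sit at different depths are separated through
parallax — the property that lets SMLFM operate at much higher emitter
densities than other 3D PSFs.

The package is aimed at microscopists and methods developers who want to

* reconstruct 3D localizations from per-view 2D localization tables,
* simulate realistic raw frames for five modalities (standard, astigmatic,
  double-helix, tetrapod and light-field PSFs) with an EMCCD noise model,
* benchmark detection quality (PPV / sensitivity / Jaccard) against ground
  truth as a function of emitter density, including the equal-error-rate
  "speed improvement" between modalities,
* link 3D localizations into tracks and estimate diffusion coefficients by
  maximum likelihood.

## Worked example

Simulate a light-field dataset at a typical dSTORM density, localize it,
and score it against ground truth:

```python
import numpy as np
from smlfm3d import benchmark, pipeline
from smlfm3d.simulate import SimConfig, simulate_dataset

ctx = pipeline.PipelineContext.create("lightfield")
cfg = SimConfig(density_per_um2=0.1, n_frames=20, photons=4000, seed=7)
ds = simulate_dataset(cfg, camera=ctx.camera,
                      optics_cfg=ctx.optics_cfg, spec=ctx.spec)
locs = pipeline.localize_stack(ds.frames, ctx)

tol = benchmark.calibrate_tolerance(ctx, 4000, seed=7)
match = benchmark.match_to_ground_truth(
    locs[locs.sigma_xy_nm < 60], ds.ground_truth, tol)
m = benchmark.compute_metrics(match)
print(f"tolerance {tol:.0f} nm")
print(f"{len(ds.ground_truth)} ground-truth emitters, {len(locs)} fits")
print(f"PPV {100*m['ppv']:.1f}%  sensitivity {100*m['sensitivity']:.1f}%  "
      f"Jaccard {100*m['jaccard']:.1f}%")
print(f"median residual {locs.residual_nm.median():.0f} nm, "
      f"median axial precision {locs.sigma_z_nm.median():.0f} nm")
```

prints

```
tolerance 153 nm
826 ground-truth emitters, 784 fits
PPV 94.5%  sensitivity 87.7%  Jaccard 83.4%
median residual 60 nm, median axial precision 29 nm
```

At 0.1 localizations/µm² the reconstruction recovers ~88% of the emitters
(sensitivity) and ~95% of its fits are correct (PPV); the 60 nm median
residual is the per-view disagreement of the parallax fit, well inside the
200 nm acceptance gate, and the ~27 nm axial precision comes from the
residual-scaled parameter covariance.

The same pipeline is available from the shell:

```bash
smlfm3d simulate --density 0.1 --photons 4000 --modality lightfield --seed 1 --out sim
smlfm3d fit2d --stack sim/stack.tif --modality lightfield --out locs2d.csv
smlfm3d reconstruct --locs locs2d.csv --out locs3d.csv
smlfm3d track --locs locs3d.csv --out tracks
smlfm3d benchmark --modalities lightfield,double_helix --densities 0.005:0.375:8
```

## Layout

| module | contents |
| --- | --- |
| `smlfm3d.optics` | lenslet geometry, parallax model, PSF models, footprints |
| `smlfm3d.simulate` | ground truth, raw frames, EMCCD noise, Brownian tracks |
| `smlfm3d.fit2d` | detection, batched Gaussian fitting, astig/DH/tetrapod 3D readout |
| `smlfm3d.lightfield` | grouping + parallax fitting, aberration/drift/axial calibration, temporal grouping |
| `smlfm3d.benchmark` | ground-truth matching, metric curves, speed improvement, FSC |
| `smlfm3d.tracking` | track linking, MLE diffusion, noise floor |
| `smlfm3d.io` / `smlfm3d.cli` | CSV/TIFF/YAML I/O, run manifests, command line |
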