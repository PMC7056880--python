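# lvotflow

Desk-scale 2D computational hemodynamics of the left-ventricular outflow
tract (LVOT): how aortoseptal-angle steepening and a discrete subaortic
stenosis (DSS) lesion alter outflow-tract flow and septal wall shear stress.

Three idealized, moving-boundary LV models are built and simulated:

| model  | description |
|--------|-------------|
| N-LV   | normal aortoseptal angle (130 deg) |
| S-LV   | steep aortoseptal angle (110 deg), same chamber |
| DSS-LV | S-LV plus a compliant subaortic lesion tab (25 % luminal reduction: 18.6 mm -> 13.95 mm) |

The package contains, one module per pipeline stage:

- `lvotflow.geometry` — parametric chamber/LVOT boundaries, septal crest
  location, the three 2-mm wall-shear site windows;
- `lvotflow.wallmotion` — synthetic cyclic wall motion (29 frames over a
  0.772 s cycle, 80 nodes, E/A filling then ejection), periodic cubic-spline
  temporal interpolation, enclosed-area waveform;
- `lvotflow.bc` — phase-switched mitral-inlet / aortic-outlet plug-velocity
  schedules from the area rate of change (diastole 0–0.480 s, systole after);
- `lvotflow.meshing` — boundary-conforming triangular meshes with graded
  wall layers, deterministic, with interior remeshing under motion;
- `lvotflow.solver` — P1 finite-element ALE projection solver for the
  incompressible (Reynolds-averaged) Navier–Stokes equations on the moving
  mesh; iterated pressure projection enforcing a scaled continuity residual
  < 1e-3 per step; exact discrete mass closure between the open boundary and
  the wall area sweep;
- `lvotflow.turbulence` — SST k-omega transport (Menter constants, strain
  production, cross diffusion, eddy-viscosity limiter);
- `lvotflow.fsi` — plane-strain Q4 lesion solid (E = 0.37 MPa, nu = 0.49,
  rho = 1100 kg/m^3), Newmark dynamics, strongly coupled partitioned FSI
  with added-mass stabilization;
- `lvotflow.endpoints` — wall shear stress tau_12 = mu(du1/dx2 + du2/dx1),
  TSM/TSG/OSI cycle metrics, vorticity, TKE/RSS, effective jet diameter,
  model comparisons;
- `lvotflow.pipeline` + `lvotflow.cli` — configuration, orchestration,
  mesh-sensitivity (velocity-profile R^2) and lesion-flutter drivers,
  VTK/CSV/JSON outputs.

Blood is Newtonian (rho = 1050 kg/m^3, mu = 0.0035 kg/(m s)).

## CLI

```sh
lvotflow build-geometry --model DSS-LV
lvotflow gen-motion --model N-LV --frames 29 --intermediate 6
lvotflow mesh --model S-LV --cell-size 1.8e-3
lvotflow run-all --model N-LV --outdir runs/nlv
lvotflow compare runs/nlv/summary.json runs/dss/summary.json
lvotflow mesh-sensitivity --model N-LV --sizes 2.6e-3,2.0e-3
lvotflow flutter --t-end 0.08
```

A run directory contains the geometry (JSON + CSV), the contour sequence
(CSV + JSON sidecar), the valve schedule (CSV), VTK field snapshots,
per-site wall-shear records (CSV), the endpoint summary (JSON) and a
manifest with the config hash and convergence diagnostics.

## Scale

Defaults are desk-scale (bulk cell 1.8 mm, ~3.7k cells, 2 cardiac cycles,
laminar closure): a three-model batch takes a few minutes on one CPU and
reproduces the directional findings (DSS jet acceleration and diameter
reduction, shear increasing toward the LVOT, steep-angle site-1 overload,
lesion flutter far above the cardiac frequency). The production-scale
settings (175 um cells, 20 um first layer, 4 cycles, SST closure) are
plain config but far slower.
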