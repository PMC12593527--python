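# pmpscan

A self-contained **virtual structured-light surface scanner** with a full
**phase-measurement profilometry (PMP)** reconstruction pipeline, built for
surface imaging studies in surface-guided radiotherapy (SGRT) and optical
metrology.  Everything runs on synthetic scenes: a deterministic ray-cast
renderer stands in for a physical camera–projector rig, so reconstruction
algorithms and rig configurations (distance, viewpoint, light intensity)
can be validated without hardware.

## What it does

A virtual projector illuminates a triangle mesh with *N* sinusoidal fringe
patterns shifted by 2π/*N*,

I<sub>n</sub>(x, y) = A(x, y) + B(x, y) cos(2π f₀ x + φ(x, y) + 2πn/N),

and a virtual pinhole camera captures 8-bit images including Lambertian
shading, projector shadows, thin-lens defocus, saturation bloom and sensor
noise.  The decoder recovers the wrapped phase in closed form,

φ = −atan2(Σ I<sub>n</sub> sin(2πn/N), Σ I<sub>n</sub> cos(2πn/N)),

unwraps it with **complementary gray codes** (period-aligned orders k₁ plus a
half-period-shifted set k₂, combined by the three-branch rule
Φ = φ + 2πk₂ for φ ≤ −π/2, φ + 2πk₁ for |φ| < π/2, φ + 2πk₂ − 2π for
φ ≥ π/2), maps absolute phase to a projector column
u<sup>p</sup> = Φ/2π · W/periods, and triangulates each camera pixel against
the projector column plane through two calibrated 3×4 projection matrices.
Calibration uses a rendered circle-grid board (5 mm fiducial and 2.5 mm
grid dots) at 20 poses, normalized DLT plus nonlinear refinement; projector
correspondences come from the absolute phase of board scans (inverse-camera
scheme).  An evaluation suite implements MAE, CMAE, symmetric Hausdorff
distance, MDTA, point-to-point ICP with RMSE, Dice overlap of voxelized
interiors, and tumor-center position error.

## Worked example

```python
from pmpscan import (ExperimentConfig, make_frustum, run_calibration,
                     run_scan)
from pmpscan.experiments import scan_metrics

config = ExperimentConfig()          # 20 mm lens, 36x24 mm sensor,
                                     # 1138x489 px camera, 1920x1080 projector,
                                     # D=400 mm, L=1000 mm, N=12, 16 periods
calib = run_calibration(config)      # renders 20 board poses (a few minutes)
print(f"camera  {calib.camera.mean_reprojection:.4f} px")
print(f"projector {calib.projector.mean_reprojection:.4f} px")

frustum = make_frustum()             # 120x120 -> 60x60 mm, 80 mm tall
cloud = run_scan(config, frustum, calib)
report = scan_metrics(cloud, frustum, config)
print(f"{len(cloud)} points  MAE {report.mae:.3f} mm  HD {report.hd:.3f} mm")
```

Output from this exact run:

```
camera  0.0054 px
projector 0.0331 px
3112 points  MAE 0.154 mm  HD 1.523 mm
```

The camera and projector reprojection residuals quantify calibration
quality (pixels); MAE is the mean absolute distance from reconstructed
points to the true surface and HD the symmetric Hausdorff distance against
a densely sampled scannable ground-truth surface (both mm) — the headline
accuracy numbers of a structured-light scan.

The same studies are scriptable from the shell:

```bash
pmpscan calibrate --out results/
pmpscan scan --fixture frustum --calibration results/calibration.yaml --out results/
pmpscan sweep-distance --out results/     # Lmm 900..1100 accuracy table
pmpscan sweep-intensity --out results/    # gain 0.5 / 1 / 2
pmpscan make-fixture torso --out torso.ply
```

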