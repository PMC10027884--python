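# arcdose

Simulation and evaluation of **linear-interpolation volumetric dose
reconstruction** from rotational planar ion-chamber-array measurements, as
used in patient-specific quality assurance of VMAT radiotherapy plans.

## The problem

Commercial QA systems verify a rotational (VMAT) delivery by inserting a 2D
ion-chamber array into a cylindrical phantom (or mounting it on the gantry)
and recording a planar dose at every gantry control point.  The 3D dose is
then rebuilt from those sparse planar samples — typically 729 to 1405
chambers at 7–10 mm pitch — by *linear interpolation* plus a
percent-depth-dose (PDD) depth model, and compared with the treatment
planning system via dose-volume-histogram (DVH) metrics.  How much accuracy
the interpolation itself costs, and how detector pitch, spatial sampling,
structure volume and tissue mass-density heterogeneity govern that cost, is
the question this package makes quantitatively testable — without any
clinical data, by supplying an analytic ground truth.

## What is in the box

| module | contents |
| --- | --- |
| `arcdose.geometry` | cartesian↔cylindrical transforms (`φ` by the three-branch arcsine rule, reduced to `[0, 2π)`), the three built-in array lattices (729-chamber 10 mm square, 1405-chamber 7.07 mm checkerboard, 1020-chamber 7.62 mm square-minus-corners), gantry rotation, voxel grids |
| `arcdose.synthetic` | analytic phantoms (water cylinder / slab, spherical density inserts 0–3 g/cm³), buildup-then-exponential PDD tables per field size, seeded VMAT-like arc plans (178- or 120-control-point arcs), the parallel-beam ground-truth dose model, voxelised ROI masks |
| `arcdose.measurement` | planar sampling of a dose at the rotated chamber positions (point or volume-averaged), per-control-point delivery, multiplicative noise and low-dose-rate (< 5 cGy/min) no-response dropout |
| `arcdose.reconstruction` | two-point linear (`φ(x) = (x−x₁)/(x₀−x₁)·y₀ + (x−x₀)/(x₁−x₀)·y₁`) and bilinear (x-then-y, equal to the weighted-area-of-four-rectangles rule) interpolation, checkerboard lattice completion, angular interpolation with full-arc wraparound, PDD depth extension, and volumetric assembly at TPS grid resolution (2.5 / 2.0 mm) |
| `arcdose.dvh` | cumulative DVHs and the ICRU-83 metric family (D98/D95/D50/D2/D1, Dmean, Dmax, V5…V50 in both `at_least`/`at_most` conventions) |
| `arcdose.evaluation` | absolute percent deviations `Pdd% = |(D_recon − D_truth)/D_truth|·100`, bootstrap confidence intervals, the Shapiro–Wilk-gated paired t / Wilcoxon test, and scripted experiments (`spacing`, `heterogeneity`, `small_volume`, `nyquist`, `dropout`) |

A thin `arcdose` command-line interface (`simulate`, `reconstruct`, `dvh`,
`evaluate`, `experiment`) wraps the same library calls; volumes are stored
as a flat little-endian binary plus a JSON header, measurements as
per-control-point CSV.

## Worked example

Reconstruct one seeded 178-control-point arc on the homogeneous cylinder
with the 10 mm-pitch 729-chamber array and compare PTV DVH metrics:

```python
import numpy as np
from arcdose import (GridSpec, get_array, make_pdd_table, make_plan, make_roi_set,
                     ground_truth_dose, measure_arc, reconstruct_volume,
                     compute_dvh, dvh_metric, metric, pdd_percent)
from arcdose.synthetic import Phantom, prescription_scale, sphere_radius_for_volume_mm

pdd = make_pdd_table()                      # 4/10/26 cm field PDD curves
phantom = Phantom(kind="cylinder")          # water cylinder, R = 135 mm
plan = make_plan(n_control_points=178, seed=1)
grid = GridSpec.centred_cube(100.0, 2.5)    # 41^3 voxels at 2.5 mm

rois = make_roi_set(grid, [{"name": "PTV", "role": "PTV", "shape": "sphere",
                            "centre_mm": (5.0, -3.0, 2.0),
                            "size_mm": sphere_radius_for_volume_mm(50.0)}])
mask = rois["PTV"].mask

truth = ground_truth_dose(plan, phantom, pdd, grid)
scale = prescription_scale(truth, mask, plan.prescription_gy)   # PTV D95 -> 60 Gy
truth.values *= scale

array = get_array("octavius729")            # 27 x 27 chambers, 10 mm pitch
ms = measure_arc(plan.scaled(scale), phantom, pdd, array)
recon = reconstruct_volume(ms, array, pdd, plan.scaled(scale), grid)

for name in ("D95", "D50", "Dmean", "Dmax"):
    spec = metric(name)
    vt = dvh_metric(compute_dvh(truth, mask), spec)
    vr = dvh_metric(compute_dvh(recon, mask), spec)
    print(f"PTV {name:<5s} truth {vt:7.3f} Gy   recon {vr:7.3f} Gy   Pdd {pdd_percent(vr, vt):.2f}%")
```

prints

```
PTV D95   truth  59.995 Gy   recon  57.705 Gy   Pdd 3.82%
PTV D50   truth  63.825 Gy   recon  63.215 Gy   Pdd 0.96%
PTV Dmean truth  63.170 Gy   recon  62.430 Gy   Pdd 1.17%
PTV Dmax  truth  64.105 Gy   recon  64.014 Gy   Pdd 0.14%
```

The cold spots of the reconstruction sit where the 10 mm lattice straddles
the field penumbra: D95, which probes the coverage edge, degrades the most,
while the flat in-field region (Dmax, D50) is nearly exact.  Rerunning with
`get_array("octavius1500")` (7.07 mm checkerboard) roughly halves the Dmean
deviation — the sampling-density effect the scripted `spacing` experiment
quantifies over 20-plan ensembles:

```bash
arcdose experiment --scenario spacing --seed 17 --out report/
```

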