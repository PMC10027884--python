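# Methods

`arcdose` studies one question: when a rotational delivery is measured as a
sequence of sparse planar chamber doses and the volume is rebuilt by linear
interpolation plus a percent-depth-dose (PDD) depth model, how large are the
resulting DVH-metric errors, and how do they scale with detector pitch,
structure size, spatial frequency content and tissue density heterogeneity?
Everything below is simulated; no clinical data enter the package.

## Coordinate conventions

Lengths are millimetres internally (centimetre inputs such as field sizes
are converted at the interface), angles radians, doses Gy.  The world frame
has the isocenter at the origin and the phantom/gantry rotation axis along
`z`.  Gantry angle `θ = 0` puts the beam along `−y`; positive angles are
counter-clockwise seen from `+z`, with a `sign` flag to flip the convention
(vendors do not agree on it).  The detector plane always contains the
rotation axis; a chamber at in-plane coordinates `(u, v)` sits at
`u·e_u(θ) + v·e_z`.  Cylindrical coordinates `(r, φ, z)` share the `z`
axis; `φ` follows the three-branch arcsine rule (0 on the axis,
`arcsin(y/r)` for `x ≥ 0`, `π − arcsin(y/r)` for `x < 0`) and is reduced
modulo `2π` so the coordinate is single-valued.  Voxel grids use the
voxel-centre convention with 0-based indices.

## Detector arrays

Three built-in lattices reproduce the commercial specifications: a 27×27
square grid at 10 mm pitch (729 chambers, 5 mm cubic cavities), two
interleaved 27×27 + 26×26 square grids offset by half a diagonal — the
unique centred layout giving 1405 chambers with 7.07 mm (= 5√2 mm)
nearest-neighbour spacing — and a 32×32 grid at 7.62 mm pitch with the four
corner chambers absent (1020 chambers) inside a 24×24 cm² area.  The
checkerboard pitch is stored exactly as `5·sqrt(2)` mm so the lattice
invariant (minimum pairwise distance equals the pitch) holds to machine
precision.

## Ground-truth beam model

Each control point contributes a **parallel beam**: dose =
`w · A(u) · A(v) · PDD(F, d_rad)/100`, where `w` is the control point's
monitor-unit surrogate, `A` a flat-top profile with logistic penumbra, and
`d_rad` the radiological depth from the phantom surface.  Design choices:

* **Parallel geometry** (no 76 cm source divergence).  Divergence rescales
  the lateral coordinate smoothly with depth; it changes nothing about the
  interpolation-error structure under study while keeping entry depths and
  chord lengths analytic.
* **Penumbra**: logistic edge with 80–20 % width 6 mm by default
  (`A(t) = σ((t+F/2)/k)·σ((F/2−t)/k)`, `k = width/2·ln4`).  Clinical 6 MV
  penumbras are 5–8 mm; the width is configurable because it sets the
  highest spatial frequency in the field.
* **PDD family**: `(1 − e^{−b·d})·e^{−μ(F)·d}`, max-normalised to 100, with
  buildup coefficient `b = 0.35 /mm` (depth of maximum ≈ 12 mm) and
  attenuation `μ(F) = 0.0060 − 6·10⁻⁵·F_cm /mm`, so larger fields fall off
  more slowly — a phantom-scatter surrogate.  Tables are tabulated at 1 mm
  steps to 280 mm for the mandatory 4, 10 and 26 cm fields; other field
  sizes interpolate linearly between bracketing curves.  Note the
  max-normalised curves cross inside the buildup region (as real PDDs do);
  the larger-field-larger-dose ordering holds beyond the depth of maximum,
  and is asserted only there.
* **Heterogeneity acts through radiological depth only**:
  `d_rad = d_geom − Σ_i (1 − ρ_i)·L_i`, with `L_i` the analytic chord of
  the ray inside spherical insert `i` upstream of the point.  Lateral
  scatter perturbation is deliberately not modelled — the phantom-based
  reconstruction method itself ignores it, and this keeps the truth
  analytic.  Densities span 0–3.0 g/cm³.
* **Plans**: evenly spaced control points (full 360° arcs omit the
  duplicate closing angle: 178 points at 360/178° steps; the slab geometry
  uses 120 by convention), per-point field sizes uniform in 4.5–7 cm and
  weights jittered ±50 % around equal weighting by default, a dose-rate
  surrogate uniform in 100–600 cGy/min, and a 60 Gy prescription imposed by
  scaling the plan so the ground-truth PTV D95 equals it.  The per-point
  schedules of clinical plans are unknown; these ranges produce in-field
  modulation and penumbras that sweep the target, which is what the
  interpolation questions need.

## Measurement model

Chambers read the analytic beam dose at their rotated centres
(`measure_arc`), or a trilinear lookup in per-control-point dose grids
(`deliver_plan`/`sample_planar`), with an optional volume-averaged mode
(3×3×3 midpoint quadrature over the chamber box).  The experiments use the
analytic route so that measurement error is purely sampling structure, not
voxel-lookup artefacts.  `apply_noise_and_dropout` adds seeded
multiplicative Gaussian noise and marks readings whose dose-rate surrogate
(the control point's nominal rate scaled by the reading relative to the
plane maximum) falls below a threshold — default 5 cGy/min — as explicit
no-response markers (NaN), never silently 0 Gy.

## Reconstruction

Per control point:

1. **Lattice completion.**  Chamber readings are placed on the axis-aligned
   bounding lattice (the checkerboard's half-step lattice for the 1405
   array).  Missing sites are filled by, in priority order: the mean of the
   four diagonal neighbours, the opposite horizontal pair, the opposite
   vertical pair — all exact for fields affine in the lattice coordinates —
   iterated until stable, with a 1D-interpolation fallback for wide dropout
   gaps.  The four absent MatriXX corners are completed by the mean of
   their two edge-adjacent neighbours (monotone; no extrapolation; not
   affine-exact, and excluded from the affine-exactness guarantee).
   Dropout policy `interpolate_over` treats no-response chambers as missing
   (the interval widens across them); `zero_fill` reproduces the
   pathological "interpolated as no response" behaviour by writing 0 Gy.
2. **In-plane bilinear interpolation** on the completed lattice (x then y;
   identical to y then x and to the weighted-area-of-four-rectangles rule).
   Queries beyond the outermost chambers clamp to the nearest node —
   linear extrapolation would fabricate gradients.
3. **Depth extension**: `dose(d) = plane(u,v) · PDD(F, d)/PDD(F, d_ref(u))`
   along the parallel ray, with `d_ref(u) = √(R²−u²)` for the cylindrical
   phantom (R = 135 mm) and a constant 120 mm for the slab geometry.  The
   reconstruction always uses the *water* PDD — exactly the model
   limitation that heterogeneous media expose.
4. **Accumulation**: contributions of all control points are summed into
   the target voxel grid (dose is additive).  The implementation evaluates
   the chamber-lattice interpolant directly at each voxel's in-plane
   coordinate and applies the depth factor analytically, rather than
   materialising an intermediate dense plane and resampling it; on aligned
   lattices the two formulations are the same piecewise-bilinear function,
   and the direct pull avoids a redundant resampling pass (the dense-plane
   operation, `densify_plane`, exists and is tested in its own right).
   Because every measured plane is reconstructed at its own angle, angular
   interpolation (`interp_angular`, periodic across full-arc closure) is
   exercised separately rather than inside the assembly.

All stages are linear in the measured values and exact at measurement
nodes; outputs never overshoot the contributing nodes (the property that
separates linear from spline schemes).

## DVH and deviation metrics

Cumulative DVHs are ≥-dose histograms over equal-volume masked voxels,
0.01 Gy bins by default, extended one bin past the maximum so the curve
reaches zero.  `D_p` is returned as the midpoint of the histogram bin that
provably contains the p-th volume-percentile voxel: a within-bin linear
refinement cannot bound its error for sparsely occupied tail bins, while
the midpoint is always within half a bin of the exact order statistic.
`Dmean` and `Dmax` come from raw voxel doses, not the binned curve.  `V_d`
defaults to the `at_least` convention (percent of volume receiving ≥ d),
which is the only reading under which lung V5/V20-style constraints make
clinical sense; the `at_most` complement is available as a switch because
table captions sometimes phrase `V_d` as "dose d or less".  Deviations are
absolute percent differences, `|(X_recon − X_truth)/X_truth|·100`, for
doses and volumes alike.

Aggregate summaries report mean, sample SD and a 95 % CI — a seeded
10⁴-resample percentile bootstrap by default (deviation samples are skewed,
and published CIs of such data are asymmetric), with a t-interval option.
Paired comparisons run Shapiro–Wilk on each sample at the 5 % level and
choose the paired t-test when both pass, otherwise the Wilcoxon signed-rank
test; raw p-values are reported with no multiplicity correction.

## Scripted experiments

All scenarios expand one master seed into per-plan seed streams
(`SeedSequence.spawn`), so comparison arms share their plan/ROI ensembles
exactly, and evaluate truth and reconstruction on a 10 cm cube at 2.5 mm
(41³ voxels) centred on the isocenter.  That region contains every ROI; the
compared DVH metrics involve only ROI voxels, so restricting the assembly
region is purely a problem-size choice (the full 27 cm phantom cube
changes nothing but the run time).  Default ensemble size: 20 plans.

* **spacing** — the same 20 homogeneous-cylinder full-arc plans measured by
  the 10 mm square array and the 7.07 mm checkerboard; compares PTV (50 cm³
  sphere, centre jittered ±10 mm) Dmean deviations.  Field sizes 4.5–7 cm
  put penumbra inside the PTV, which is where pitch matters.
* **heterogeneity** — homogeneous vs lung-insert phantom on identical
  plans.  Two conditions differ from the spacing defaults, for a physical
  reason: with a *full* arc, the water-assumption error of two opposed
  beams enters as reciprocal factors `e^{±μΔ}` about the isocenter plane
  and cancels to second order in the PTV mean (for a purely exponential
  PDD the upstream-insert error cancels exactly), so the scenario uses a
  half arc (90 control points over 180°, matching the control-point
  density of the full arc; clinical deliveries routinely use partial
  arcs), and fields of 7–10 cm keep the PTV fully in-field so penumbra
  interpolation error does not mask the density effect.  The lung-like
  insert (sphere, r = 30 mm, ρ drawn per plan from 0.01–0.26 g/cm³)
  overlaps the PTV — the "low-density tissue surrounding a lung lesion"
  configuration.  These settings were fixed from physical reasoning during
  design, not fitted to any threshold.
* **small_volume** — Dmax deviation of a 0.2 cm³ sphere (lens-scale,
  r ≈ 3.6 mm, placed at 30 mm lateral offset where the 4.5–7 cm field
  edges sweep) versus a 50 cm³ central sphere, 10 mm array, 20 seeds.
* **nyquist** — a planar field `B + A·cos(2πu/T)` sampled by the 10 mm
  lattice and densified.  The recovered-amplitude estimator is the mean
  relative error of the reconstruction *at the true modulation crests*
  inside the chamber hull (crest aligned with the array centre).  This is
  the deliberate choice among several defensible estimators: any spectral
  measure of the interpolant is attenuated by `sinc²(h/T)` even above the
  sampling limit (≈ 19 % at T = 40 mm, h = 10 mm) and so cannot separate
  the regimes, whereas crest recovery measures exactly the peak-structure
  loss the sampling-theorem argument concerns: at T = 15 mm (below the
  20 mm limit) two of every three crests alias onto troughs (≈ 75 % mean
  error), at T = 40 mm every crest coincides with a chamber column and is
  reproduced exactly.
* **dropout** — low-dose-rate dropout (5 cGy/min) applied to the readings,
  comparing the `interpolate_over` and `zero_fill` policies on PTV Dmean.

## Numerical choices and degenerate inputs

Coincident interpolation nodes, degenerate bilinear cells, empty ROI
masks, all-no-response planes, angles outside a partial arc, depths or
field sizes outside the PDD table, and densities outside 0–3 g/cm³ all
raise errors naming the offending object.  At `r = 0` the azimuth is
defined as 0.  Chamber/voxel coordinate arithmetic keeps node queries exact
to ≲ 10⁻¹³ relative even for the irrational 7.62/7.07 mm pitches.
Reference depths with vanishing PDD (grazing rays at the cylinder edge)
contribute zero rather than dividing by zero.

## What the generator does not emulate

MLC aperture shapes, tongue-and-groove and output-factor effects, source
divergence, contaminant electrons, detector energy/angular response,
recombination and calibration factors, inclinometer error, lateral scatter
perturbation by heterogeneities, and the fluence-correction loop of
model-based commercial systems.  Consequently, passing tests demonstrate
the *sampling and interpolation* behaviour of the reconstruction chain
under controlled conditions — orderings and scalings (pitch, volume,
frequency, density) — not the absolute clinical deviation magnitudes of any
commercial device, which depend on the unmodelled physics above and on real
patient anatomy.
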