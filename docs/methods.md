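# Methods

## Scope and intent

`letplan` is a synthetic, desk-scale re-creation of a three-way IMPT
planning comparison: nominal optimization, objective-wise worst-case robust
optimization, and LETd-based optimization, evaluated for dosimetric
quality, robustness bandwidth, and biological effect. Everything runs on
generated voxel phantoms; the package makes no claim of dosimetric accuracy
for real patients — its purpose is to expose the *structural* trade-off
between robust target coverage and target LETd under controlled,
reproducible conditions.

## Phantoms

Phantoms are piecewise-geometric: a cylindrical head (radius 60 mm) of soft
tissue (relative stopping power 1.0) with a 4 mm bone annulus (1.5) and air
outside (0.001); a cylindrical brainstem and a thinner spinal cord
continuing inferiorly; and a CTV whose shape defines the archetype:

* `wraparound` — a C-shaped annular segment (default arc 250°) around the
  brainstem; the inner radius is calibrated by a deterministic scan so the
  CTV covers 22% (±3 points) of the brainstem voxels, the outer radius by
  bisection on the discrete grid so the CTV volume lands within 5% of the
  55.27 cc target;
* `abutting` — a prolate ellipsoid (z-aspect 2.3) touching the brainstem
  surface, 56.67 cc;
* `inferior_extension` — a cylinder on the brainstem axis reaching 18 mm
  below the caudal end of the brainstem and overlapping the spinal cord,
  40.88 cc.

The grid is 3×3×3 mm (44×44×50–56 voxels). Default brainstem/cord
dimensions are chosen so their voxel counts land near the reference triples
of the three emulated cases (391/127, 719/473, 739/95). Construction is a
pure function of the spec: the only "search" steps are deterministic
bisections against voxel counts. The voxel-count and volume goals cannot
both be met exactly for the CTV (55.27 cc at 3 mm is ~2047 voxels); the
volume target is authoritative.

Coordinate convention: 0-based indices, world = origin + (index+0.5)·voxel;
axis 0 right→left, axis 1 posterior→anterior, axis 2 inferior→superior.

What the phantoms do **not** emulate: realistic CT texture, tissue
interfaces away from the skull annulus, inter-patient anatomical variation,
and air cavities near the target. Passing tests therefore demonstrate the
behaviour of the optimization formulations, not clinical dosimetry.

## Beam and influence model

Each spot has an analytical central-axis depth-dose curve in
water-equivalent depth `z` for nominal range `R`:

```
d(z) = 0.24·(1 + 0.0012 z)·½ erfc((z−R)/√2 σ) + exp(−(z−R)²/2σ²),
σ(R) = hypot(0.0139·R^0.935, 2 mm),
```

normalized to a unit peak. The erfc factor terminates the plateau at the
peak; σ combines range straggling with a fixed beamline energy-spread
floor, which also keeps the curve well sampled on the 3 mm grid. The
companion LET curve is a logistic rise from 0.9 keV/µm at the entrance to
15 keV/µm just distal of the peak (rise scale 2.5 mm) — monotone by
construction, matching the qualitative LET-depth behaviour of clinical
proton energies. The lateral profile is a single Gaussian of width
σ_lat = 2.5 mm + 0.04·depth, integral-normalized.

Radiological depth is computed by resampling the density on a
beam's-eye-view grid (1.5 mm lateral, 1 mm depth steps), cumulating along
the beam axis, and interpolating back at voxel centers; on a uniform water
box this reproduces geometric depth to machine precision for axis-aligned
beams. Range uncertainty multiplies this line integral (equivalent, at this
fidelity, to perturbing beam energy); setup uncertainty shifts the
isocenter by the negative of the patient shift.

Spots are placed on a 5 mm lateral grid over the CTV's beam's-eye-view
footprint with 5 mm water-equivalent energy-layer steps spanning each
lateral position's CTV depth interval. Influence entries below 10⁻⁴ of the
spot's peak stored dose are dropped; D and L share one sparsity pattern.
The planning pipeline computes influence only on the union of structure
voxels (≈2–3k rows), which is what every objective and every reported
metric consumes; full-grid rows are available for diagnostic use.

## Optimization

The dose objective is a sum of mean squared one-sided deviations of the
constant-RBE dose (1.1 × physical): target underdose and overdose about the
54 Gy(RBE) prescription, and per-OAR overdose above 60 (brainstem) / 57
(spinal cord) Gy(RBE). OAR limits are soft quadratic penalties with
post-hoc acceptability checks (D95 ≥ 51, maxima under the limits) rather
than hard constraints. The LET objective adds `−(φT/NT) ΣT Li²
+ (φO/NO) ΣO Li²` on the nominal scenario only, with the OAR sum over the
union of brainstem and cord voxels; zero-dose voxels contribute zero value
and gradient. The robust objective takes the per-term maximum over the nine
scenarios, with ties broken at the lowest scenario index; its gradient sums
the active scenarios' term gradients.

Solver: L-BFGS-B with nonnegativity bounds and analytic gradients
(interior-point is not required by anything in the formulations; any
bound-constrained quasi-Newton method honoring the monotone-descent
contract serves). Initialization is uniform intensity scaled so the mean
CTV constant-RBE dose equals the prescription — deterministic, so runs are
bit-reproducible. Default iteration cap 400, ftol 1e-10.

Penalty weights are per-archetype configuration (`src/letplan/configs`),
hand-tuned once per archetype — mirroring how clinical planners fine-tune
weights per case — so that all three strategies meet the acceptability
thresholds after normalization and the study's qualitative orderings are
expressed. The LET priorities φT/φO are the main dials: φO must be large
enough that the LET plan actually suppresses the brainstem LETd maximum,
but raising φO alone also drains target LETd (the target shares beam paths
with the OARs), so φT rises with it; the `inferior_extension` case, where
the CTV overlaps the spinal cord, needs the largest values.

## Uncertainty model

Nine scenarios: one nominal, six single-axis setup shifts of ±2.25 mm, two
range scalings of ±3.5%. All scenarios are equally weighted (the worst-case
composition uses no probabilities). A patient shift +s is realised as an
isocenter shift −s; only the symmetry of the ± set is relied upon. Robust
optimization consumes all nine; nominal and LET optimization use the
nominal scenario only, and every plan is re-evaluated under all nine.

## Biology

Constant RBE is the clinical 1.1 factor. Variable RBE uses the McNamara
et al. (2015) linear-quadratic model with (α/β)x = 10 Gy for the target
and 2 Gy for OARs, evaluated at the per-fraction dose (total/30); the
published coefficients are configuration data so alternative fits can be
swapped in, and the tests pin qualitative properties (monotone in LETd,
larger for smaller (α/β)x) rather than coefficient values. The linear
surrogate is `D·(1 + c·LETd)` with c = 0.04 µm/keV; its `c·LETd·D` term is
reported as the LET-dependent biological dose component.

## Evaluation conventions

* Every plan is normalized so its nominal-scenario CTV D95 (constant RBE)
  equals 54 Gy(RBE); dose is linear in intensity so the rescale is exact
  and LETd is unchanged (degree-0 homogeneity).
* D95 is the sort-based quantile: the largest value received by ≥95% of
  structure voxels.
* LETd statistics zero the LETd wherever the constant-RBE dose is ≤ 1 Gy;
  means include the zeroed voxels. Both choices (RBE-weighted threshold,
  zeros-in-mean) are conventions configurable at the call site; the dose
  quantity for the threshold is genuinely ambiguous and the RBE-weighted
  reading matches the Gy(RBE) reporting convention used everywhere else.
* Robustness of a statistic = (worst-case min, worst-case max, bandwidth)
  across the nine scenarios.
* Per-beam decomposition restricts both the dose sum and the LETd quotient
  to one beam's columns; per-beam doses sum to the total exactly.

## Problem sizes and determinism

The default experiments use ~100k-voxel grids, 2.6–4.3k spots over 3–4
beams, and structure-restricted influence matrices of ~1.5–3M nonzeros per
scenario; one archetype (phantom through evaluation, nine scenarios, three
plans) completes in roughly one to one-and-a-half minutes on a single CPU.
These sizes were chosen as the smallest at which the three geometries
remain anatomically distinct and the scenario shifts (2.25 mm) stay below
the voxel pitch. All stages are deterministic; the seed is recorded in the
run manifest and threaded to the solver options for provenance, though no
stage draws random numbers.

## Known limitations

* The analytical beam model has no nuclear halo, no heterogeneity-driven
  lateral scattering, and a schematic absolute LET calibration; LETd values
  are in the right regime (≈1–10 keV/µm) but not machine-specific.
* Objective-wise worst case is the only robust composition implemented
  (voxel-wise and composite variants are not).
* No combined robust+LET optimization; the two strategies are compared as
  separate Pareto solutions.
* OAR constraints are penalties; pathological weight choices can trade
  acceptability for objective value, which is why shipped configurations
  are validated by the acceptance checks.
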