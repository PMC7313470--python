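# Methods

This note documents the models, algorithms, and numerical choices behind
`retinamech`, and what the synthetic-data tests do and do not demonstrate
about real measurements.

## 1. Synthetic experiment generator

No raw stretching data are publicly deposited, so the package generates the
two raw-data types the analysis consumes.

**Calibration tables.** Extensions follow Hooke's law,
`x_i = m_i g / k_true + ε_i`, with `g = 9.81 m/s²`, a default true spring
constant of 54.96 N/m (the glass-fiber pair of the force sensor), ten masses
spanning the 150–2200 mg brass-wire range, and Gaussian camera-tracking
noise (default SD 2 µm) on the extension channel.

**FD curves.** The noiseless mean curve is a five-piece function of motor
displacement d:

* toe, `d ≤ toe_end = 0.01 mm`: the cubic `k₁·toe_end·(u² − u³/3)` with
  `u = d/toe_end`.  It starts at zero force with zero slope, and reaches
  slope k₁ with zero curvature at `toe_end`, so the join into regime 1 is
  C² and the toe cannot bias a regime-1 slope fit.  Any smooth monotone
  "nonlinear force increase" would do; this is the simplest one with the
  right boundary behaviour.
* regime 1: a line of slope k₁ up to the first yield force F_y1;
* regime 2: a constant plateau at F_y1, of length 200 µm;
* regime 3: a line of slope k₃ up to F_y2;
* regime 4: a constant plateau at F_y2, up to `d_max = 1 mm`.

Corners are exact (no rounding): it is the simplest shape consistent with
the described regimes, and the segmentation has to tolerate corners anyway.
Noise is additive zero-mean Gaussian on force only (default SD 0.02 mN;
sensor noise dominates, and no drift model is warranted by the data
description).  All generators take a mandatory seed; identical inputs are
bit-identical.

**Rate presets.** The printed anchors are k₁ = 21.5 N/m, F_y1 = 1.5 mN at
2.0 µm/s and k₁ = 33.5 N/m, F_y1 = 2.2 mN at 0.1 µm/s.  The 0.5 µm/s preset
interpolates linearly in rate between the anchors; k₃ = 2 k₁ and
F_y2 = 2.5 F_y1 throughout, since the regime-3/4 levels were only ever shown
graphically.  Every non-published value is listed in the preset's
`invented` field, and rates outside 0.1–2.0 µm/s are flagged
`extrapolated`.  Rate dependence is purely phenomenological — presets encode
the measured level shifts; no viscoelastic constitutive model is attempted.

What passing tests on these curves show: the *pipeline* recovers the
parameters it was pointed at, under the stated noise, grid, and corner
geometry.  What they do not show: robustness to drift, displacement jitter,
rounded yield shoulders, rate-dependent noise, or tissue-to-tissue geometry
variation, none of which the generator emulates.

## 2. Sensor calibration

Ordinary least squares of gravitational force `F = m g` on measured
extension, with a free intercept.  The slope is the spring constant k; the
intercept absorbs any constant offset in the dot-tracking reference and is
reported as a diagnostic only — conversion of extensions to forces uses
`F = k x` alone.  A free intercept costs nothing when the data are truly
proportional and protects the slope when they are not.  Degenerate tables
(all extensions equal) and non-positive slopes raise typed errors.  With the
default mass grid and 2 µm noise the estimator is unbiased to well under 1%
(the errors-in-variables attenuation from noise on the regressor is of
order (2 µm / 115 µm)² ≈ 3·10⁻⁴, negligible).

## 3. Regime segmentation

The model is a *continuous* piecewise-linear function with four breakpoints
(toe boundary, first yield, plateau-2 end, second yield), parameterised so
that each piece's slope is a separate coefficient: column j of the design
matrix holds the length of piece j's interval covered up to x.  Structural
admissibility is part of the objective: a configuration is admissible only
if the fitted slopes have positive rises and plateau slopes within 10% of
the preceding rise.  The fitted minimum is therefore the global minimum of
the SSE over admissible breakpoint tuples on the sample grid, which an
exhaustive brute-force oracle verifies on short records in the test suite.

Search: the toe/regime-1 boundary is initialised at the known 0.01 mm toe
end; the remaining breakpoints are initialised by an exhaustive dynamic
program over per-segment OLS costs in which rising regimes are free lines
and plateaus are constants (computable for all segment pairs at once from
cumulative sums).  Coordinate descent on the continuous-model SSE then
refines each breakpoint within a ±12-sample window per pass until no move
improves the fit.  The typed initialisation matters: an unrestricted search
happily spends a breakpoint chasing noise in the long final plateau while
absorbing the narrow toe into regime 1, mislabeling every downstream
parameter.  Records longer than 2000 samples run the DP on a strided
subsample; the refinement window covers the stride.

Parameter extraction deliberately re-fits on regime interiors rather than
reusing the piecewise coefficients: k₁ and k₃ are OLS slopes over the
samples strictly inside their regimes (two samples of margin at each
breakpoint; samples below 0.01 mm excluded from k₁), plateau forces are
interior means, and the yield forces F_y1/F_y2 are the maximum measured
force within ±5 samples of the corresponding breakpoint — the observed
force maximum at the transition, robust to corner rounding, rather than a
line intersection.  On noiseless generated curves this recovers the
generator parameters to machine precision; under the default noise the max
estimator of the yield force is biased high by ≈ E[max of 11 Gaussians]
≈ 1.7 σ ≈ 0.03 mN, well inside the experimental replicate scatter.

Curves with no admissible configuration (e.g. a plateau-free straight line)
fall back to the unrestricted fit, flagged `no_yield_detected`, with
plateau slopes clamped by a bounded least-squares pass.  Partial records
(tests stopped mid-way) are fit with a reduced number of pieces and flagged
`partial`.  Replicates at one rate are summarised as mean and sample SD
(n − 1 denominator; zero for n = 1).  Optional moving-average pre-smoothing
exists but defaults to off: smoothing must not bias slopes on clean input.

## 4. Forward finite-element model

Geometry: two scaffolds, each 3 × 10 × 0.1 mm, side by side along x with
gap 0 by default; the retina, 6 × 10 × 0.22 mm, bonded on top of both.
Materials: isotropic linear elasticity; titanium scaffolds at
E = 105 GPa, ν = 0.33 (standard handbook values — the scaffolds are ~10⁸×
stiffer than the tissue, so their exact moduli are immaterial); retina at
ν = 0.49 with E the free parameter; density 1017 kg/m³ is carried in the
configuration but unused (static solve, no body force).  Boundary
conditions: every node of one scaffold clamped (which also pins the retina
bonded to its top face); the moving scaffold constrained to u_z = 0; a
uniform x-traction on the moving scaffold's outer 10 × 0.1 mm sidewall,
summing to the configured load (default 1.0 mN).  Readout: mean
x-displacement u_x of the loaded sidewall (the plate deforms by ~10⁻⁸ of
the retina, so any consistent readout agrees); `load / u_x` is the
structural stiffness comparable to measured k₁.

At zero gap the coincident scaffold–scaffold faces carry duplicated,
unconnected nodes, so the plates interact only through the retina; the
retina additionally keeps its own nodes along the interface line, bonded to
each scaffold's top strictly on that scaffold's side.  Open-gap
configurations (`gap > 0`) mesh the gap as void and need no duplication.

Discretisation: structured, axis-aligned 8-node hexahedra; full 2×2×2 Gauss
quadrature with the mean-dilatation (B-bar) treatment of the volumetric
strain rows — the standard selective-reduced-integration remedy for
volumetric locking at ν → ½.  Verification: uniaxial patch test (roller +
pin constraints, uniform traction) exact to 10⁻¹⁴ relative at ν up to
0.499; thin-layer simple shear against F = G·A·δ/t to 0.04% with four
elements through the thickness; external work equals stored energy;
displacement exactly linear in load; E·u_x constant to < 0.5% over
E ∈ [100, 5000] Pa.

The mesh is graded geometrically (ratio 1.35) toward the scaffold
interface, where the deformation localises, with the smallest in-plane cell
equal to the retina's element height.  Resolution level L uses 3L elements
through the retina thickness, 6L along the depth, and a maximum cell of
2.4/L mm; the production level is L = 4 (≈ 33 000 dofs, ~20 s per solve on
one CPU), and level 6 (≈ 10⁵ dofs) remains within a desktop budget.  Tests
use L = 1–2 (seconds).

Solver: sparse LU (SuperLU) on the symmetrically Jacobi-scaled reduced
system with a few steps of iterative refinement.  The 10⁸ stiffness
contrast sets a rounding floor for the *evaluated* residual near 10⁻⁶ in
the scaled norm even though the displacement readout is stable to ~10⁻⁶
relative between refinement steps; the solver therefore accepts residuals
up to 10⁻⁴ and reports the achieved value.  Displacement fields can be
exported as ASCII VTU for inspection.

### The zero-gap model has no mesh-converged stiffness

With gap = 0 and the retina bonded up to the interface on both sides, a
rigid translation of the moving plate imposes a displacement *jump* on the
retina's bottom surface along the interface line.  The elastic energy of
such a discontinuous boundary trace diverges logarithmically with the
resolved length scale — the same way a dislocation's energy diverges with
its core cutoff.  Empirically the model reproduces this cleanly: at
E = 760 Pa the structural stiffness rises by ≈ +1.1 N/m for every halving
of the interface cell size (4.6, 5.7, 6.3, 6.8 N/m at levels 1, 2, 3, 4)
with no limit.  Physically the cutoff is supplied by finite strain and by
the finite gap that opens during the measurement itself; within linear
elasticity at zero gap it is supplied by the mesh.  Consequently:

* the 3%-per-doubling mesh-convergence criterion is satisfiable for open-gap
  configurations (verified at gap = 0.2 mm) but *not* at the default
  zero-gap geometry, where u_x still drifts ≈ 16% per level pair at
  practical resolutions;
* any reference displacement computed for this configuration is a property
  of the reference's discretisation as much as of the continuum problem.
  A locking-prone discretisation (full integration at ν = 0.49, or linear
  tetrahedra at 1–2 elements through a 0.22 mm layer) is stiffer by a
  factor 2–3 at these mesh sizes: we measure full integration 2.1× stiffer
  than B-bar on a medium hex mesh, while at ν = 0.3 (no locking) the two
  agree within 5%.  The locking-free model at L = 4 gives
  u_x ≈ 147 µm at E = 760 Pa under 1.0 mN (k ≈ 6.8 N/m), and the inverse
  identification maps the measured slopes 21.5 / 33.5 N/m to ≈ 2400 /
  3750 Pa.  It is also worth noting that E/G = 2(1+ν) = 2.98 at ν = 0.49:
  results quoted from near-incompressible models should state explicitly
  whether the identified parameter is a Young's or a shear modulus, because
  the two differ by exactly the factor a locking-free/locking comparison
  produces here.

The package reports what the locking-free continuum model computes and does
not tune the mesh toward any external displacement value.

## 5. Inverse modulus identification

The target is either a (load, displacement) pair or a measured slope k_exp,
converted to displacement `u* = load / k_exp` at the fixed reference load of
1.0 mN (immaterial by linearity; fixed for reproducibility).  Because the
scaffolds are effectively rigid, u_x(E) ≈ c/E, so after one probe solve at
E₀ = √(lo·hi) of the bracket (default [10, 10⁵] Pa) the scaling iterate
`E₁ = E₀·u_x(E₀)/u*` lands within a fraction of a percent; secant updates
on log E polish to the requested relative tolerance (default 10⁻³).
Convergence takes ≤ 3 forward solves in practice (≤ 6 guaranteed by the
near-proportionality), and u_x is strictly decreasing in E so the iteration
cannot stall inside the bracket.  All solves of one inversion share one
mesh and one assembled pair of stiffness contributions
(K = K_scaffold + E·K_retina), eliminating discretisation bias between
iterations and re-solve cost except the factorisation.  Forward→inverse
round trips on the same mesh recover the modulus to < 10⁻³ relative.
No uncertainty propagation from the slope SD to E is attempted; the rate
table reports point identifications per displacement rate.

## 6. Pipeline and reproducibility

`run_pipeline` executes calibrate → generate/ingest → segment → summarise →
invert from one YAML-serialisable configuration with a single seed; every
stage writes its artifact (CSV/JSON) to the output directory, the resolved
configuration is copied alongside, and the report carries the package
version and a configuration hash but no timestamps, so identical runs are
byte-identical.  Replicate counts default to the experimental design (five
at 0.1 µm/s, three each at 0.5 and 2.0 µm/s).  Stage failures abort with
the failing stage named; partial artifacts are retained.

## 7. Problem sizes

Chosen as the package's own defaults: segmentation Monte-Carlo at 20 seeds
× 1000 samples per rate; calibration Monte-Carlo at 50 seeds (500 in the
bias check); FE production resolution L = 4 (~33 k dofs), benchmark and
round-trip tests at L = 1–2; the exhaustive segmentation oracle at 80-point
records, where full enumeration of admissible breakpoint quadruples is
feasible.

## 8. Known limitations

* Linear kinematics: local strains near the interface are O(1) in the real
  experiment at measurable displacements; geometric stiffening is outside
  this model, which together with the zero-gap singularity means the
  identified "effective" modulus is tied to the stated discretisation and
  geometry conventions.
* The generator's corners are exact and its noise is white; real curves
  have rounded shoulders and drift the segmentation has not been stressed
  against.
* Camera-image processing is out of scope: dot positions enter as given
  time series.
* Plateau physics (stick–slip of ruptured layers) is represented only as
  constant-force segments, not modelled mechanistically.
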