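# retinamech

Tensile mechanics of adult mammalian retinae on a two-scaffold tissue
stretcher: force-sensor calibration, force–distance regime segmentation, and
inverse finite-element identification of the retina's effective Young's
modulus.

## The problem

Adult porcine retinae can be stretched ex vivo on a pair of TiO₂-nanotube
scaffolds: the tissue adheres to both scaffolds, one scaffold is pulled away
by a stepper motor at constant velocity (0.1–2.0 µm/s), and the force is read
from the elongation of a glass-fiber spring attached to the stationary
scaffold.  The resulting force–distance (FD) curves show a reproducible
five-part shape:

1. a nonlinear **toe** below 0.01 mm (loose clamping, entropic network
   effects),
2. a **linear elastic rise** (regime 1) whose slope k₁ [N/m] is the
   structural elastic constant,
3. a first yield at force F_y1 followed by a **constant-force plateau**
   (regime 2, ≈ 200 µm long; sliding of ruptured retinal layers),
4. a **second, steeper linear rise** (regime 3, slope k₃), and
5. a **second plateau** (regime 4) after the second yield F_y2.

Because the two scaffolds initially touch, the stretched length is not
measurable and k₁ cannot be converted to a Young's modulus by dividing
stresses by strains.  Instead, the modulus is identified *inversely*: a 3D
small-strain linear-elasticity model of the full stretcher (two stiff
titanium plates, the near-incompressible retina bonded on top, ν = 0.49) is
solved repeatedly, varying the retinal modulus E until the simulated
sidewall displacement under the measured load matches the measured
compliance, u_x = F / k₁.

This package implements every stage as tested, seedable code, including a
synthetic-experiment generator that stands in for the (undeposited) raw
data, so the whole analysis runs end-to-end from a clean checkout.

The finite-element solver is written here on top of `numpy`/`scipy.sparse`:
trilinear hexahedra with mean-dilatation (B-bar) selective reduced
integration of the volumetric term, the standard remedy for volumetric
locking at ν → ½.  It passes a machine-precision uniaxial patch test and a
simple-shear benchmark against F = G·A·δ/t.

## Worked example

```python
from retinamech import (fit_spring_constant, segment_regimes,
                        estimate_modulus, InverseTarget)
from retinamech.synthetic import (generate_calibration_table,
                                  generate_fd_curve, make_rate_preset)

# 1. calibrate the glass-fiber force sensor (10 brass masses, 150-2200 mg,
#    2 um camera tracking noise)
table = generate_calibration_table(54.96, noise_sd=2e-6, seed=11)
spring = fit_spring_constant(table)
print(spring.summary())

# 2. segment one noisy FD curve recorded at 2.0 um/s
curve = generate_fd_curve(make_rate_preset(2.0), n_points=1000,
                          noise_sd=0.02e-3, seed=11)
fit = segment_regimes(curve)
print(fit.summary())

# 3. identify the effective modulus that reproduces the fitted slope
result = estimate_modulus(InverseTarget.from_slope(fit.k1), resolution=2)
print(result.summary())
```

prints

```
Glass-fiber spring calibration (OLS, free intercept)
  n points    : 10
  k           : 55.3558 N/m
  SE(k)       : 0.2699 N/m
  intercept   : -9.072e-05 N (diagnostic)

FD-curve regime segmentation (continuous piecewise-linear LSQ)
  samples          : 1000
  rate             : 2.00 um/s
  breakpoints [um] : 5.0, 73.1, 273.3, 325.3
  k1 (regime 1)    : 21.591 N/m
  F_y1             : 1.536 mN
  k3 (regime 3)    : 42.945 N/m
  F_y2             : 3.771 mN
  SSE              : 3.998e-07 N^2

Inverse modulus identification (scaling iterate + log-secant)
  E_hat          : 2883.8 Pa
  forward solves : 2
  residual       : 6.29e-07 (relative)
  bracket        : [10, 100000] Pa
  converged      : True
```

Reading the numbers: the calibration recovers the true spring constant
(54.96 N/m) within its standard error; the segmentation recovers the
generator's regime-1 slope (21.5 N/m) and first yield force (1.5 mN) to
within the noise; and the inverse identification converges in two forward
solves because the sidewall displacement is almost exactly inversely
proportional to the retinal modulus.  The identified modulus depends on the
mesh resolution near the scaffold interface — see `docs/methods.md` for why
this model has no strict mesh-converged stiffness at zero scaffold gap and
how that interacts with comparisons against locking-prone discretisations.

A command-line interface wraps the same stages
(`retinamech simulate|calibrate|segment|invert|run`); `retinamech run
--config config.yaml --out DIR` executes the full pipeline (calibration →
curves → segmentation → replicate summaries → per-rate inversion) and
writes a versioned JSON report plus all intermediate artifacts.

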