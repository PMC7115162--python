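# Methods

## Retrieval model

The Water Cloud Model treats the corn canopy as a homogeneous water cloud
over a scattering soil surface. For one polarization,

    σ⁰(L, Mv, θ) = A·L^E1·cosθ·(1 − τ²) + (C·Mv + D)·τ²
    τ²           = exp(−2·B·L^E2 / cosθ)

with L the biomass (kg m⁻²), Mv the volumetric soil moisture (m³ m⁻³), θ the
incidence angle (stored in degrees, converted to radians internally) and σ⁰
the backscatter in **linear power units** — never decibels; explicit
dB↔power helpers exist but are never applied implicitly. The two-way
transmissivity τ² divides by cosθ in *both* places it appears: that is the
canonical form of the model, and the slant path through the canopy is the
same whether the wave is scattered by the canopy or by the soil below it.
Published typesettings of the model sometimes drop the division in the
canopy term; we treat that as a typographical artifact.

The model is evaluated with either wet or dry biomass as L (a configuration
choice, default wet — both are legitimate and field datasets carry both).
HH and HV calibrations must use the same choice for the inversion to be
meaningful, and the coefficient files record it.

## Calibration

Each polarization's six coefficients (A, B, C, D, E1, E2) minimize the sum
of squared backscatter residuals over the calibration points. The solver is
a classic damped (Levenberg–Marquardt) least-squares loop written in this
package (`sarbiomass/_optim.py`), with the analytic Jacobian of the forward
model. Choices:

- **Starting point.** Coefficients start from a uniform(0,1) draw, seeded.
  Because the WCM surface has multiple basins, the default runs 20 restarts
  and keeps the best SSE; every restart's initial and final SSE is retained
  for diagnostics and logging.
- **Stopping.** Iteration stops when the SSE *decrease* of an accepted step
  falls below `tol` (default 1e-8) or after `max_iter` (default 100)
  iterations. An absolute SSE target would be meaningless for noisy field
  data; the decrease criterion is what iterative nonlinear regression
  routines actually implement.
- **Minimum data.** Six coefficients need at least six points; fewer raise
  an error. A constant biomass column makes the canopy coefficients
  rank-deficient and raises a warning.
- **Why an own LM loop rather than scipy.** Three reasons: the stopping
  rule above is not scipy's (`ftol` is relative); the same engine also
  solves the 2×2 inversion with a step-size stopping rule and trains the
  transfer network, where MINPACK's LM cannot be used at all (17 residuals
  < 31 parameters); and the test suite deliberately cross-checks this loop
  against `scipy.optimize.least_squares` as an *independent* oracle, which
  only means something if the implementation is independent. On noise-free
  synthetic data the two optimizers agree in SSE to better than 1e-10.
- **Zero-residual fits.** For recovery tests on noise-free data the default
  `tol=1e-8` stops too early (the SSE itself is already ~1e-9 near the
  solution); such tests pass `tol=1e-18`, which lets the quadratic
  convergence run down to machine precision. Field-data fits gain nothing
  from this.

A caution that the package surfaces rather than hides: on real field data
the HH (soil-dominated) fit is quasi-unidentifiable. The SSE keeps
decreasing along an unbounded valley in which B and E2 grow jointly while
B·L*^E2 stays fixed — the attenuation turns into a step function in L — so
the least-squares problem has an infimum that is never attained. Fits
stopped at different points of this valley predict almost identically inside
the data range; coefficients themselves should not be interpreted
physically. This is why all recovery contracts in the tests are stated in
prediction space, not coefficient space.

## Inversion

With calibrated HH and HV coefficients, each observation gives the 2×2
system {σ⁰_HH(L, Mv) = obs_HH, σ⁰_HV(L, Mv) = obs_HV}, solved by the same
damped least-squares engine from the fixed start (1.0 kg m⁻², 0.2 m³ m⁻³),
stopping when the step between iterates drops below 1e-6 or after 400
iterations. Numerical choices:

- The solver works on the smooth even extension σ⁰(|L|, Mv) so fractional
  powers stay real if an iterate crosses zero; −L* and +L* are then the
  same root and the non-negative branch is reported. No other clamping is
  applied: a root with Mv outside [0, 1] is reported as found, with
  `physical=False`.
- `converged` requires three things: the step criterion fired, the residual
  norm is ≤ 1e-8 (a root was actually found, not just a stall), and the
  retrieval Jacobian at the solution is identifiable (condition number
  < 1e10). Degenerate cases — e.g. B = 0, where biomass drops out of both
  equations entirely — converge to the correct Mv but are flagged
  `identifiable=False` and not counted as converged.
- On real data some observations lie outside the image of the calibrated
  forward pair, so no root exists; these return `converged=False` and are
  flagged, never fatal, matching how the pipeline treats them.

## Optical models and indices

All four vegetation-index models are linear in their two coefficients once
the index is transformed (exp, identity, log, identity), so the iterative
fit — run with the same uniform(0,1) start and stopping rule as the WCM for
procedural consistency — lands on the ordinary-least-squares solution; the
tests assert agreement to 1e-8. Index formulas from band reflectance
(NDVI, SR, SRre, RTVI) are the literature-standard defaults and are
overridable, because sensor-specific variants of RTVI exist; the primary
calibration path takes precomputed index values, as the packaged dataset
supplies NDVI directly. Eight independent model objects cover
4 forms × {wet, dry}.

## Transfer network

A 1–10–1 network: one input (SAR biomass estimate), 10 tanh hidden units,
linear output. "Two-layer" in the curve-fitting sense: one hidden plus one
output layer. Inputs and targets are min-max normalized to [−1, 1] over all
supplied pairs (the standard preprocessing of toolbox fitting networks; the
scalings are stored in the network so a saved network is self-contained).
Weights start from a seeded uniform(−1, 1) draw and are trained by
Levenberg–Marquardt on the training split, stopping on gradient or step
below 1e-7 or at 1000 iterations. Of n pairs, ceil(0.7·n) are used for
training — 23 pairs give the 17/6 split — with membership shuffled by the
seed; the holdout is used only to report `holdout_mse_` (normalized scale),
never for early stopping. Applied outputs are denormalized and passed
through an absolute value, so adjusted biomass is non-negative by
construction; because tanh saturates, any output is bounded by a constant
computable from the output weights and scalings (`output_bound()`).

## Synthetic data generator

The generator emulates the structure of the field dataset: (L, Mv, θ) drawn
uniformly over configurable ranges whose defaults are the calibration
dataset's spans (wet biomass 0.04–7.1 kg m⁻², soil moisture 0.039–0.379
m³ m⁻³, incidence 21.025°–31.9592°); backscatter from the WCM forward
operator times unit-mean lognormal noise (multiplicative, speckle-like,
keeps σ⁰ > 0); NDVI by inverting a configured index model plus additive
noise, clipped to [−1, 1]; dry biomass as a fixed fraction (0.125, the
dataset's mean ratio) of wet.

Default generating coefficients were chosen once, as physically plausible
C-band corn values with HH soil-dominated and HV vegetation-dominated
(A=0.08, B=0.10, C=0.60, D=0.06, E1=0.3, E2=1.0 for HH; A=0.020, B=0.60,
C=0.03, D=0.003, E1=0.6, E2=0.5 for HV). Complementary channels matter: they
keep backscatter positive over the whole domain, in the magnitude range of
field data, and — checked on a 300-point scan — make the two-equation system
uniquely solvable inside the ranges, which is the premise of a dual-pol
retrieval. The default noise CV of 0.05 represents field-averaged
backscatter (many pixels averaged per point), and the default NDVI noise SD
is 0.02. The default table size is 23 points, the calibration sample size
the method was designed around.

What the generator does *not* emulate — and therefore what passing recovery
tests do not demonstrate: model error (real canopies are not uniform water
clouds; the generator's backscatter is exactly WCM plus noise), spatial
correlation between points, incidence-angle/biomass correlation from orbit
geometry, growth-stage-dependent moisture content (the dry:wet ratio is
fixed), and saturation of NDVI in closed canopies beyond what the
exponential model implies. Recovery on synthetic data validates the
estimation machinery, not the physics.

## Pipeline

`run_all` chains the stages: calibrate HH and HV on the calibration rows;
invert every point; fit the configured optical models on calibration rows;
train the transfer network on calibration-row (SAR estimate → optical
estimate) pairs; apply it (with abs) to validation-row SAR estimates. The
first configured optical form feeds the network (default the NDVI
exponential model, since the packaged table carries NDVI). Outputs are one
CSV row per validation point with all flags, serialized model files per
stage, and a log with seeds, per-restart SSEs and solver exit reasons. Runs
with identical configuration are byte-identical.

## Known limitations

- The HH field-data calibration is quasi-unidentifiable (see above);
  retrieved coefficient values are not physically interpretable, and
  real-data inversions can converge to roots far outside physical ranges,
  which are flagged rather than suppressed.
- The retrieval accuracy on the packaged dataset is not itself a tested
  contract — no reference accuracy statistics are packaged — so the test
  suite asserts structural and recovery properties (synthetic round trips,
  split conventions, flags, determinism), not field-data RMSE.
- The transfer network is a 1-input map; covariates (angle, moisture) would
  require widening the input layer, which the implementation permits
  structurally but does not expose.
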