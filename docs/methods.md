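# Methods

`capsulesim` simulates the locomotion of a capsule endoscope that propels
itself by electrically stimulating the smooth muscle of the small
intestine.  A pair of electrodes on the capsule body contracts the
surrounding gut wall; because the contraction pressure acts normal to the
capsule's sloped exterior, a fore–aft asymmetry of the pressure field
produces a net axial force.  The package predicts the contraction
pressure field, the force balance (moving force, friction, drag) and the
capsule's motion over time, and reproduces the design studies built on
that forward model (exterior-shape sweeps, the three-capsule comparison,
and electrode-placement optimisation).

## Model

### Geometry

The capsule is an axisymmetric solid of revolution of length `L` whose
radius profile rises exponentially from a tip radius `r` toward a
maximum `R` with slope constant `α`, mirror-symmetric about `L/2`:

    f(x) = (R − r)(1 − e^{−αx}) + r,          0 ≤ x < L/2
    f(x) = (R − r)(1 − e^{α(x−L)}) + r,       L/2 ≤ x ≤ L

`α` multiplies the axial coordinate, so it carries units of 1/length; a
value of 0.3/mm is the conventional slope of the studied capsules.  The
profile is C0 but not C1 at `L/2`; the derivative there is taken as the
average of the two (equal-and-opposite) one-sided slopes, i.e. zero,
which removes the undefined point from all integrands and is numerically
immaterial for realistic `α`.

Bundled presets (all with an 11 mm maximum diameter, `R` = 5.5 mm,
`α` = 0.3/mm, `L` = 26 mm): **type 1** `r` = 3 mm, **type 2** `r` = 2 mm,
**type 3** `r` = 4 mm (a blunt control).  `L` is not a published quantity
for these capsules; 26 mm is a conventional telemetry-capsule length and
`L` is a required configuration field, so no silent default enters a
reported run.

### Passive tissue mechanics

The intestine is a thin-walled viscoelastic cylindrical vessel of
resting diameter `d0` and wall thickness `h` that the capsule distends.
Circumferential strain is

    εc(x) = max(0, 2 f(x)/d0 − 1),

reading the local distended diameter as `2 f(x)`.  (The literal printed
form of the source model divides the radius by a diameter, which makes
a capsule exactly filling the lumen carry negative strain; the
diameter-ratio reading is the only physically consistent one.  The
literal form remains available as `strain_mode: literal`.)

Under held strain the wall stress relaxes as a two-exponential-plus-
plateau spectrum

    σc(t) = εc · s · (0.7 e^{−t/18} + 0.63 e^{−t/1.6} + 0.92)   [kPa],

with `t` the time since the tissue was first strained, and the thin-wall
relation converts stress to the passive pressure on the capsule,
`Pi = (2h/d) σc` with `d = 2 f(x)` taken pointwise.  The spectrum's units
are not stated by its source, and a second printed variant of the same
spectrum, (7, 6.3, 5) kPa, is not a consistent rescaling of the first
(the plateau would be 9.2, not 5).  We therefore default to the measured
spectrum with a single dimensionless modulus scale `s` (`stress_scale`)
and keep the alternative behind `relaxation_mode: alternative`.

### Stimulated contraction

The plateau ("maximum") contraction pressure follows a Hill-type
logistic in stimulus amplitude `As` (V) scaling a frequency-linear
maximum in `fs` (Hz):

    Pm = (0.24 fs + 1.18) / (1 + (As / 4.97)^{−3.72})   [kPa].

This grouping makes `Pm → 0` as `As → 0` and half-maximal at 4.97 V,
matching the sigmoid amplitude response of the calibration experiments;
an alternative grouping in which only the intercept is amplitude-gated is
exposed as `grouping: additive` for traceability.  Pulse duration (5 ms,
twice the smooth-muscle chronaxie) was never varied in the calibration
data and is echoed in reports but is not a model covariate.

The contraction develops first-order in time,
`dPs/dt + Ps/τs = Pm/τs`, `Ps(0) = 0`, with rising time constant
`τs = 17.3 s` (measured 17.3 ± 8.3 s); τs is by definition the time to
reach 63.2% of the plateau.  Spatially the stimulated pressure is a
Gaussian footprint centred on the electrode position `x0`,

    G(x) = 1.4 e^{−(x−x0)² / (2ω)},

which travels with the capsule.  The footprint variance is reported as
0.22 with no units; we read it as 0.22 cm² (FWHM ≈ 11 mm), commensurate
with 5 × 6 mm electrodes — a mm² reading would make the footprint far
smaller than the electrode itself.  The 1.4 prefactor is the calibrated
ratio between the locally peaked pressure and the catheter-averaged
plateau, so the local target pressure is `Pm · G` unnormalised.

### Force balance

The total tissue pressure `Ps + Pi` acts normal to the surface.  With
`θ(x) = π/2 − arctan f′(x)` the surface slope angle, the normal pressure
is `P1 = (Ps + Pi) sin θ`, clamped at ≥ 0 (contact, not adhesion), and

    F_m = 2π ∫ P1 cos θ f √(1+f′²) dx        (signed axial moving force)
    F_f = 2π μ ∫ P1 sin θ f √(1+f′²) dx      (friction magnitude)
    F_d = b v                                 (Stokes drag)
    F_t = F_m − F_f − F_d.

With `θ` from the signed slope, `cos θ` is positive on the rising rear
ramp and negative on the falling front ramp, so a symmetric pressure
field cancels exactly and a cylinder (`f′ ≡ 0`) generates no moving
force regardless of pressure: the exterior shape alone decides whether
the capsule can move.  The friction coefficient is the measured
`μ = 0.1`.  At rest, friction is capped at the driving force (a stiction
clamp), the standard regularisation that keeps a capsule whose friction
exceeds its moving force at rest instead of numerically chattering.

The drag coefficient `b` is either a user constant (default
0.5 mN·s/mm) or a thin-film annular lubrication surrogate
`b = 2πη ∫ f/(c − f) dx`, `c = R + film`, justified by the observation
that at creeping speeds the exterior shape barely affects drag.  No
published value of `b` exists for these capsules, so absolute velocities
carry a calibration degree of freedom; relative velocities between
shapes do not (at steady state `v = (F_m − F_f)/b`, and `b` cancels from
velocity ratios).

### Time stepping

A fixed-step explicit Euler loop (default `dt` = 1 ms) advances, per
step: (1) each lab-grid node's `Ps` first-order toward its moving target
`Pm G(x − x0(t))` — rising with `τs`, and decaying with the same
constant once the footprint moves on (the source model specifies only
the rise; symmetry of the first-order model is the default, and a
separate `tau_fall_s` is exposed); (2) stretch clocks, started when the
capsule first strains a node and not reset while contact persists;
(3) the force balance and `a = F_t/m`; (4) velocity and position.  The
lab grid spacing is 0.25 mm with a margin of ten footprint standard
deviations on each side, auto-extended as the capsule travels.  The
forward model is deterministic.

Capsule mass is never published for these capsules; the bundled configs
use 3.8 g (a conventional telemetry-capsule mass) and document it as a
calibration input.  Peristalsis is omitted: the stimulated contraction
dominates it by design.  The model is direction-symmetric, so it cannot
reproduce oral/aboral speed differences.

## Calibration of unpublished constants

`d0`, `h`, `stress_scale`, `b` and mass are free inputs of the published
model.  The bundled defaults — `d0` = 8 mm, `h` = 0.6 mm,
`stress_scale` = 5, `b` = 0.5 mN·s/mm, mass 3.8 g, 6 V / 10 Hz / 5 ms
stimulus, electrode 5 mm from the rear edge — were chosen once, before
any acceptance checks, on these grounds: `d0` and `h` are plausible
no-load dimensions for porcine small intestine; `stress_scale` = 5 lies
between the two published spectrum scalings (1× and ~10×) and is the
regime in which the blunt type-3 control capsule reproduces its reported
immobility; `b` and mass are conventional figures that keep the explicit
Euler loop comfortably stable (`m/b` ≈ 8 ms ≫ `dt`).  Under these
defaults the type-1 capsule travels at ≈ 2.2 mm/s, consistent with the
reported in-vitro 2.91 ± 0.99 mm/s (which is not a verification target —
it is a wet-lab measurement with the uncalibrated `b`/mass freedom).

## Design-study metrics

The electrode-placement study uses mean net acceleration over the first
10 s (equivalently, the velocity reached by 10 s divided by the window).
A shorter "initial" window is degenerate: with `τs` = 17.3 s and the
stiction clamp, no capsule breaks away before ~5 s, so any window inside
that is identically zero for every offset.  Ten seconds spans breakaway
at the optimum while remaining short against the full contraction rise.
The type comparison uses steady velocity: the mean velocity over the
trailing 10 s of a 60 s run, by which time the travelling contraction
field has reached its quasi-steady profile.

## Known discrepancy in the type comparison

The published design comparison states that the type-2 capsule (r = 2 mm)
is 23% slower than type 1 (r = 3 mm) and has the larger internal volume.
Both statements are incompatible with the model equations themselves:

* the solid-of-revolution volume strictly increases with tip radius at
  fixed `R`, `α`, `L`, so type 2 has the *smaller* volume;
* for any pressure field shared by the two shapes, the propulsive
  integrand `P·f·f′/√(1+f′²)` of the r = 2 mm shape dominates the
  r = 3 mm shape pointwise (for x > 0.3 mm) while its friction integrand
  `P·f/√(1+f′²)` is pointwise smaller — and the contraction field `Ps`
  is shape-independent — so type 2 is strictly *faster*.  Simulations
  confirm this across wide ranges of the free tissue parameters (the
  deficit is −25% to −50%, never +23%).

A single swap of the type-1/type-2 labels would make both published
statements consistent with the model (and with the published observation
that more streamlined capsules are faster).  The package keeps the
presets as printed, reports computed velocities and volumes, and attaches
explicit caveat notes to every type-comparison report rather than
silently correcting either claim.  The reported type-3 immobility and
the 5 mm electrode-placement optimum are reproduced.

## Numerical choices

* Surface and volume integrals: composite Simpson on 501 uniform nodes
  (configurable); tests pin them against 10×-refined quadrature and a
  10⁶-slice midpoint oracle.
* The trig factors use the algebraic forms `cos θ = f′/√(1+f′²)`,
  `sin θ = 1/√(1+f′²)`, so the cylinder limit is exactly zero.
* Explicit Euler at `dt` = 1 ms; halving `dt` or the grid spacing
  changes the steady velocity by < 0.01% at the defaults.
* Dose–response fitting: trust-region-reflective nonlinear least squares
  with five seeded multistarts (the Hill exponent induces local minima);
  standard errors from the Gauss–Newton curvature at the solution.
  Rank-deficient designs (fewer than 2 frequency or 3 amplitude levels,
  or constant response) are rejected with informative errors.
* Rising-time estimation: least squares on `Pm(1 − e^{−t/τ})` with a
  63.2%-crossing initial guess.
* Synthetic data: additive Gaussian noise on peak pressures (no residual
  structure is published); rising time constants drawn from a normal
  truncated below 1 s.  Byte-reproducible given (protocol, seed).

## What the synthetic generator does and does not emulate

It reproduces the published calibration protocol's design — a
10/20/40 Hz × 2–10 V grid at fixed 5 ms pulses with ~0.2 kPa peak-
pressure noise, and 20 rise curves with τs ~ 17.3 ± 8.3 s — under ideal
assumptions: i.i.d. Gaussian noise, no muscle fatigue, no inter-subject
correlation, no drift.  Passing recovery tests therefore demonstrates
estimator correctness and calibration consistency, not robustness to the
structured variability of real tissue preparations.

## Limitations

* Straight, uniform lumen; no meandering path or wrinkled segments.
* Direction-symmetric: no oral/aboral asymmetry.
* No electrode-size/impedance model (the footprint is fixed), no muscle
  fatigue, no spontaneous post-stimulus contractions.
* Drag is a scalar Stokes coefficient, not a CFD solution.
* Absolute velocities depend on the uncalibrated `b`/mass inputs; only
  orderings and relative differences are meaningful without additional
  calibration.
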