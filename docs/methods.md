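# Methods

## Scope and model structure

`oxyflux` models steady, coupled O2/CO2 transport in blood flowing past a
gas-exchange membrane. The package deliberately replaces the device-scale
geometry of a real oxygenator (thousands of fibers in a staggered bundle)
with a reduced 2D slit channel: a membrane wall at `y = 0`, a symmetry
plane (or mirrored wall) at `y = half_gap`, and a prescribed axial velocity
profile. This keeps the nonlinear coupled physics — which lives entirely in
the closures — at desk scale, while flow resolution around individual
fibers is out of scope.

The physiology layer is pointwise and algebraic: given (PO2, PCO2) it
returns pH, saturations, contents, their derivatives and the effective
diffusivities. The solver consumes only these closure functions, so the
physiology can be validated independently of any grid.

## Physiological submodels and assumptions

**Acid–base.** pH and bicarbonate solve the Henderson–Hasselbalch relation
simultaneously with the Van Slyke buffer line at base excess 0. The
non-carbonic buffer power is linear in hemoglobin,
`beta_NC = 1.43·Hb[g/dL] + 7.7` (mmol/L per pH unit). Substituting the
buffer line into Henderson–Hasselbalch leaves a scalar equation in pH,
smooth and strictly monotone on the physical branch, solved by
Newton–Raphson from pH 7.4 with the analytic derivative (tolerance 1e-10 on
the residual, max 50 iterations). Iterates that leave the physical branch
fall back to bracketed root finding on (5.5, pH_max), where
`pH_max = 7.4 + 24.4/beta_NC` is the zero-bicarbonate asymptote of the
buffer line; this bracket contains the root for every PCO2 in the clamped
domain (the root sits near 8.3 at the 0.5 mmHg floor and near 6.8 at
250 mmHg, so any fixed narrow bracket around 7.4 would fail).
`pKa = 6.082` is the package default: it reproduces pH 7.357 at
PCO2 = 44 mmHg for Hb = 0.118 g/mL, the venous reference condition; the
textbook 6.09 can be configured.

**Oxygen.** The Kelman quartic rational maps a Bohr-adjusted pressure to
saturation. The adjustment exponent `0.024(37−T) + 0.40(pH−7.4) +
0.06·log10(40/PCO2)` uses base-10 logarithms throughout (the decimal
structure of the exponent fixes this reading). The raw rational is
slightly negative below ~4 mmHg adjusted pressure (its leading numerator
coefficient is negative); output is clamped to [0, 1] and the analytic
slope is zeroed in the clamped region.

**Carbon dioxide.** Carbamino saturation is a Hill curve with
P50 = 265 mmHg and exponent 0.9942, evaluated at a Haldane-adjusted
pressure with exponent `0.004(37−T) + 1.66(pH−7.4) + 0.02·log10(100/PO2)`.
Bicarbonate content converts to volumetric units with 0.02226 mL CO2/mL
blood per mmol/L, applied exactly once at the acid–base boundary. The
reported total CO2 content uses the McHardy correction
`C_HCO3·[1 − c·Hb/((2.244 − 0.422·SO2)(8.74 − pH))]`. Two circulating
coefficient/unit conventions of this formula differ by a factor of ten in
the correction term; the package defaults to `c = 0.02924` with Hb in g/dL
(the grouping of the original whole-blood correction, giving a ~16%
correction at venous conditions rather than ~1.6%), with the weaker
variant selectable as `as_printed`. Dissolved CO2 is not added to the
McHardy value by default (the formula is bicarbonate-based); an opt-in
flag adds it.

**Derivatives.** All slopes are analytic: the Kelman and Hill rational
derivatives chain through the (pressure-independent) adjustment factors,
and the bicarbonate slope follows from implicit differentiation of the
acid–base system, `dpH/dPCO2 = −(1/(PCO2·ln10)) / (1 + beta_NC/(C·ln10))`.
The test suite checks every analytic slope against central finite
differences at 1e-6 relative tolerance.

The CO2 saturation slope is offered in two modes. `frozen_pH` is the bare
Hill-chain partial derivative and is strictly positive. `buffer_line`
(the default, because pH in this model is a function of PCO2 only) adds the
pH feedback — and is *negative* over most of the physiological range: the
1.66 pH coefficient of the Haldane adjustment, multiplied by the
acidification rate dpH/dPCO2, outweighs the direct pressure rise (e.g.
−4.3e-4 /mmHg at PCO2 = 44, PO2 = 35.9). This is a genuine property of the
fitted curves, not a numerical artifact; physically, acidification
displaces CO2 from hemoglobin faster than pressure loads it. The carbamino
weight in the CO2 effective diffusivity is therefore slightly negative in
the default mode; it is two orders of magnitude smaller than the
bicarbonate weight, and the effective diffusivity remains inside the
min/max bounds of its three constituent diffusivities across the
physiological range (asserted in tests).

**Clamping.** Physiology is evaluated on the box PCO2 ∈ [0.5, 250] mmHg,
PO2 ∈ [0.01, 760] mmHg. The clamp is load-bearing: the CO2 wall boundary
condition is 0 mmHg, exactly where the Bohr logarithm and the
Henderson–Hasselbalch relation are singular. Clamp events are counted and
carried through solutions and reports.

## Membrane and rheology

Gas transport through the microporous fiber wall is Knudsen-dominated.
The wall is characterised by a measured permeance Km
(cm³ STP/s/cm²/cmHg: 1.08e-3 for O2, 1.40e-3 for CO2); the equivalent
diffusivity of an explicitly meshed membrane region is
`D = Km·(tau/eps)·h·(T/T0)·P0` with tortuosity 4, effective porosity 0.5,
wall thickness h = 90 µm, referenced to 298 K and 760 mmHg. The grouping
is fixed by a consistency requirement: a slab of thickness h and pore
fraction eps/tau with this D must reproduce exactly the measured permeance
flux Km·ΔP at the reference state — `wall_permeance` is that inverse and
feeds the Robin (series-resistance) wall mode of the solver, the reduced
domain's alternative to meshing the membrane. The grouping factors sit in
`MembraneSpec`, so alternative readings are testable without code changes.

Blood rheology is Carreau–Yasuda with density 1050 kg/m³. The shear
parameters (mu0 0.056 Pa·s, mu_inf 0.00345 Pa·s, lambda 3.313 s, a 2,
n 0.3568) are standard literature whole-blood values, not device-specific
measurements; they enter only the flow-descriptor helpers, since the
channel velocity profile is prescribed, not solved.

## Transport solver

The physics is the content conservation law per species,
`div(u·C(P)) = div(Gamma(P)·grad P)`, where `C` is the total carried
content and `Gamma = Σ D_i·w_i` the content-flux coefficient whose ratio
to the capacity `dC/dP = Σ w_i` is the familiar effective diffusivity.
The solver discretizes this *undivided* form: first-order upwind
convection of the content (linearised per Picard sweep as
`C(P) ≈ C(P_k) + dC/dP|_k (P − P_k)`), central diffusion with
harmonic-mean face coefficients, Dirichlet inlet, convective outflow,
Dirichlet or Robin membrane wall, symmetry or mirrored wall at the
centerline. Axial diffusion is on by default. Under-relaxation 0.7,
outer tolerance 1e-6 on the relative field change, iteration cap 200,
divergence declared after 10 consecutive residual growths. CO2 is updated
before O2 within each sweep, so each species' closure sees the other's
latest field. Sparse systems are solved directly. No randomness anywhere;
runs are reproducible up to floating-point associativity.

The choice of the undivided form is deliberate. Dividing by the capacity
yields the one-field pressure equation usually quoted, but the capacity
varies by two orders of magnitude across the O2 boundary layer (the
dissociation slope collapses on the saturation plateau), and discretizing
the divided form breaks content conservation badly: on the reference
channel the measured wall-flux/mixed-cup imbalance was ~3x the transfer
itself for O2, versus ~3e-4 for the conservative form. The conservative
scheme balances content to solver tolerance by construction — the cell
balances telescope to boundary fluxes.

One consequence: because the convected O2 content depends on PCO2 through
the Bohr shift, rapid CO2 stripping near the wall can transiently lower
PO2 below the inlet value (the left-shifted curve holds the same content
at lower pressure) — a small "Bohr dip" of a few percent. The pressure
fields are therefore only approximately monotone toward the walls for the
coupled closure; the uncoupled closures satisfy a strict maximum
principle.

**Closures.**
* `coupled` — the full physiology above.
* `frozen_o2_curve` — a fixed Hill O2 curve with no Bohr response, in the
  style of fixed-saturation-curve oxygenator models. Default P50 and
  exponent are fitted to the Kelman curve at standard conditions (exact at
  50% saturation and at 60 mmHg; maximum deviation < 0.03 between those
  points). The CO2 side stays coupled.
* `constant_co2_slope` — a linear CO2 content curve in the style of the
  classical constant-slope CO2 models: the chord slope of the coupled
  content over the 25–50 mmHg window (at the inlet PO2, along the buffer
  line) and the window-averaged flux coefficient, making Deff,CO2
  independent of the local state. The source model publishes no parameter
  values, so this chord construction is the package's own. The O2 side
  stays coupled.
* `linear_tracer` — constant-property passive tracer for verification
  against closed forms.

**Verification.** The plug-flow constant-property channel is checked
against the slit Graetz eigenfunction series: 0.04% mixed-cup error on a
400x80 grid, observed convergence order 1.2–1.3 (first-order upwind limits
the order from above the diffusion-dominated value of 2). Conservation is
checked on every reported run (≤1% required, ~3e-4 typical); trivial
limits (uniform state, pure diffusion, zero length) are exercised in the
test suite.

On the reference channel with shared boundary data, the frozen O2 curve
yields a higher outlet O2 content than the coupled closure (it lacks the
near-wall Bohr left-shift that throttles uptake), and the constant-slope
CO2 closure substantially overpredicts outlet CO2 content — both asserted
as directional regression properties of the implemented closures.

## Reference conditions and problem sizes

The default configuration is the package's reduced stand-in for a small
in-vitro oxygenator test: channel length 16 mm (the bundle length),
half-gap 90 µm (about half the clearance between neighbouring fibers),
width 1 cm for flow bookkeeping; venous inlet (PO2 35.9 mmHg ⇒ SO2 0.65,
PCO2 44 mmHg), membrane wall at 707.7 mmHg O2 and 0 mmHg CO2; five flow
conditions at superficial velocities 0.34–1.70 cm/s corresponding to
100–500 mL/min. The default grid is 120x40 with geometric wall grading
1.06; the test suite uses 48x20–80x30 grids for coupled runs and up to
400x80 for the linear Graetz benchmark — sizes chosen so the full suite
verifies every property in well under a minute per module while keeping
discretization error comfortably inside the asserted tolerances.

The fixture generator emits velocity fields, the five-flow config sweep
and physiology curve tables from constants alone. What it does *not*
emulate: real velocity fields around staggered fibers (wakes, stagnation
zones), hematocrit heterogeneity and the near-wall cell-free layer,
pulsatility, temperature fields (T is a scalar parameter), or 2,3-DPG
shifts of the dissociation curve. Passing tests therefore demonstrate the
correctness of the coupled physiology and of the transport scheme on the
reduced geometry — not device-scale transfer-rate prediction.

## Known limitations

* Single-phase blood: no red-cell migration or cell-free layer.
* The channel is a geometric surrogate; absolute transfer rates scale
  with the configured width/half-gap and are not device predictions.
* The curvature-driven source terms of the pressure-form equations are
  carried only as a diagnostic (their neglect is standard and the
  transport scheme does not need them).
* The acid–base system assumes base excess 0 and fixed pKa; no
  temperature dependence of pKa or solubilities.
* First-order upwind convection is robust but diffusive; the wall-graded
  grid compensates where gradients are steep.
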