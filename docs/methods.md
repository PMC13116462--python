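# Methods

## Physical model

One well of a 96-well plate (diameter 6.4 mm) sits on a grounded copper
plate.  A needle electrode 0.5 mm above the liquid ignites a microplasma
that contacts the buffer surface at the well centre; a sinusoidal high
voltage (20 kHz, 20 kV peak-to-peak, v(t) = A·sin(2πft + φ) with φ = 0 at
treatment onset, configurable) drives current through buffer, cell
monolayer and dish bottom.  The plasma path is approximated as a perfect
conductor: the source attaches only to the buffer-top node of the innermost
ring, and the air above all outer rings insulates them.  Nonlinear or
time-varying plasma impedance, waveform distortion (spike transients),
plasma chemistry (RONS), heating, and dispersive material properties are
all out of scope; the estimated thresholds are therefore *effective*
parameters of this idealization.

### Discretization

The well bottom is divided into 40 concentric rings with widths R/128
(rings 1–4 and 37–40), R/64 (5–6 and 35–36) and R/32 (7–34); the integer
width scheme sums to exactly R, so the rings tile [0, R] machine-exactly.
Ring quantities are attributed to the midpoint radius (an area-weighted
centroid is available).  `region_at_radius` uses half-open rings
[inner, outer) with the outermost ring closed.

### Circuit composition

Per ring (area A, heights/thicknesses and material constants below):

| element | formula | value source |
|---|---|---|
| buffer vertical R | H_s/(σ_s·A) | H_s = 0.1 mm, σ_s = 0.172 S/m |
| membrane C (top and bottom) | ε_m·A/T_m | T_m = 7.5 nm, ε_m = 5ε₀ (default) |
| cytoplasm vertical R ∥ C | H_c/(σ_c·A), ε_c·A/H_c | H_c = 10 µm, σ_c = 1 S/m, ε_c = 30ε₀ |
| dish C | ε_d·A/H_d | H_d = 1.5 mm, ε_d = 2.4ε₀ |

Adjacent rings are linked radially inside the buffer (annular-log
resistance ln(r_{n+1}/r_n)/(2π·σ·H) between ring centres, exact for purely
radial flow) and inside the cell layer.  The membrane permittivity is not
tabulated with the other constants of this system; 5ε₀ is a typical lipid
bilayer value and is an explicit, configurable default rather than a hidden
constant.  Membrane conductivity defaults to 0 (intact membrane as ideal
dielectric); a nonzero value adds a parallel conductance.  The cytoplasm
conductive thickness is taken as H_c (T_m/H_c < 0.1%, negligible).

**Lateral cell-junction capacitance.**  A confluent monolayer has no
continuous lateral cytoplasm conductor: radial current inside the cell
layer crosses the apposed membranes of neighbouring cells.  Each ring
boundary therefore carries, in series with its radial cytoplasm
resistance, a junction capacitance ε_m·(2π·r_b·H_c)/(2·T_m) (two lateral
membranes in series over the cylindrical interface).  This choice was
forced by the physics, not aesthetics: with a plain radial resistor the
lateral cytoplasm path short-circuits the layer, the dose peaks off-axis
at a radius comparable to the buffer depth, the monotone-dose premise of
the radius inversion fails, and predicted death radii collapse onto the
well wall (2.5–3.1 mm) — far from the sub-1.5 mm dead zones this kind of
experiment produces.  With the junction capacitance the dose is maximal on
the axis, decays monotonically, and death radii land in the observed
regime.  The plain-resistor variant is kept as
`element_values(..., lateral_junctions=False)` for comparison.

### Solvers

Complex nodal analysis at the drive frequency: admittances G = 1/R and
jωC, ground and the driven node eliminated, dense LU solve (~240 nodes —
no sparsity machinery warranted) with mixed-precision iterative
refinement.  The relative residual ‖Yv − i‖/‖i‖ is ~10⁻¹² and is reported
on the solution.  Per-node Kirchhoff balance is additionally audited; in
float64 it bottoms out near 10⁻⁷ at the insulating rim, where nA-scale
through-currents are differences of kV-scale node voltages — an intrinsic
cancellation floor, not a solver defect.

An independent brute-force oracle integrates the same network in the time
domain (trapezoidal rule, A-stable, zero initial state).  Network time
constants are far shorter than one drive cycle, so cycles 5–6 are
periodic; phasors fitted there agree with nodal analysis to well under 1%
on every cytoplasm branch (at 800 steps/cycle; capacitor currents are
recovered by differentiating branch voltages, which needs the finer step).
Energy conservation (mean source power vs summed resistive dissipation) is
audited to 0.1%.

### Dose field

Vertical cytoplasm current density: total (conduction + displacement)
branch current over the ring area.  Radial: boundary current over the
cylindrical lateral area 2π·r_b·H_c, averaged over the ring's two
boundaries (single boundary for rings 1 and 40); boundary-value
alternatives differ by O(Δr).  σ in p = J²/σ is the cytoplasm conductivity.
Dose integration uses the steady-state waveform from t = 0; startup
charging transients are ignored (they decay within a small fraction of the
first cycle here, and the transient solver quantifies the effect if
needed).  Waveforms are sampled at 1024 points/cycle by default, so gating
times are quantized at ≤ 1/1024 cycle.

### Death models and radius inversion

The gated accumulation ∫ p·H(p − P_th) dt is evaluated on the sampled
instantaneous waveform (not on cycle averages), with H(0) = 1 so that
p exactly at the gate accumulates.  Because the waveform is periodic,
whole periods contribute the per-period gated energy and only the final
partial period needs the cumulative integral — the cost of a time-to-death
query is independent of its answer.  One-Step is literally Two-Step with
P_th = 0, so the reduction identity is bit-for-bit by construction.
"Never reached" is an explicit censored value (`None` scalar / `inf` in
profile arrays), never a sentinel magnitude.

The per-ring time-to-death profile T*(r) is inverted into a death radius
by linear interpolation between the bracketing ring centres (nearest-ring
snapping available).  The inversion presumes a disc-shaped dead zone,
i.e. T* non-decreasing in radius; the check tolerates 2% relative ripple,
which covers the ~0.1% discretization ripple the non-uniform width scheme
leaves at its transitions, and raises on anything larger.

### Threshold fitting

Objective: Σ over durations of (model radius − observed mean radius)²,
equal weights, evaluated at the experiment's durations.  "Agreement on
linear and logarithmic time axes" is served by the log-spacing of the
durations themselves; a log-axis re-weighting would change the
visualization, not the residuals.  Replicate SDs are carried for reporting
only (no weighting scheme is defined for these data).  Default grid:
P_th ∈ [0, 20] µW/mm³ step 0.5, W_th ∈ [0.05, 1.0] µJ/mm³ step 0.05 —
bracketing the reference values with headroom — followed by one local
refinement at 5× resolution (±1 coarse step).  Exact ties break toward
smallest P_th then smallest W_th, making the fit deterministic.  A
dataset of all-zero radii is flagged degenerate and returns the boundary
solution (W_th at the grid maximum).

Identifiability: W_th shifts the whole curve and is sharply identified
(standard error ≈ 0.35 refined steps at radius noise SD 0.02 mm, n = 4).
P_th only shapes the approach to saturation (0.2–4 µm of radius per
refined step across the duration grid), so its standard error is ≈ 2.7
refined steps under the same noise; per-duration replication at this
noise level cannot pin P_th to one refined step.  Noiseless on-grid data
are recovered exactly.

### Effective P_th for short durations

For each duration ≤ 10 ms, bisection finds the P_th at which the forward
Two-Step radius equals the observed one (the radius is non-increasing in
P_th, so the root is well defined when bracketed), to 0.5% of the bracket
width.  The default bracket reaches 400 µW/mm³: matching strongly
suppressed short-duration radii requires gating away a large fraction of
each cycle in rings where p greatly exceeds the base threshold, which
pushes the root to 10–30× the base value.  Unbracketable targets are
flagged non-convergent and carry no value.

## Synthetic experiments

The generator emulates the structure of the radius-vs-duration experiment
this pipeline consumes: durations {2, 3, 4, 6, 8, 10, 20, 30, 40, 50,
100} ms; per duration the mean radius is the forward Two-Step prediction
and n = 4 replicates add homoscedastic Gaussian noise (default SD
0.02 mm, small against millimetre radii), truncated at zero; everything is
reproducible from a seed.  An optional short-duration suppression shrinks
radii multiplicatively below 10 ms (default strength in tests: 0.25 per
decade); it exists to exercise the effective-P_th estimator, not as a
claim about biology.  The generator does **not** emulate: image analysis
of the fluorescence boundary, inter-experiment (day/passage) variability,
heteroscedastic or correlated replicate noise, or any chemical
contribution to death.  Passing tests therefore show pipeline
self-consistency under the stated statistical structure, not validity on
real wells.

## Numerical choices

- SI units internally everywhere; µ-units (µW/mm³, µJ/mm³, mm, ms, kHz)
  only at I/O boundaries.
- Trapezoidal quadrature throughout (waveform energy, gated accumulation,
  transient integration); crossing times by linear interpolation.
- Thresholds exactly at a sampled plateau edge are knife-edge cases: the
  sampled crossing can land one burst later than the exact-arithmetic one
  (tested as a lower bound, not an equality).
- Grids are built from exact binary-representable steps (500 W/m³,
  50 J/m³) so on-grid truth is recovered bit-exactly.
- Netlist export writes SIN source, R and C cards with node 0 as ground;
  any SPICE-class simulator can replay the network.  Within this package
  the transient integrator plays that cross-validation role.

## Known limitations

- The circuit topology is a reconstruction (ladder + radial links +
  junction capacitance); absolute dose magnitudes, and hence fitted
  thresholds, are conditional on it and on the assumed membrane
  permittivity.
- The dose field is piecewise-constant per ring; radii are only defined
  up to a ring width (interpolation smooths but cannot add information).
- Only the fundamental drive frequency is modelled; real discharge
  currents contain fast transients that would raise instantaneous power
  through the capacitive paths.
- The death models are deterministic thresholds; no cell-to-cell
  variability, recovery dynamics, or time-dependent P_th(t) functional
  form is fitted (the per-duration effective P_th is an empirical probe,
  not a parametric model).
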