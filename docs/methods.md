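# Methods

`lvcomp` is a reduced-order model of the pressure-overloaded rat left
ventricle (LV) built to ask one question quantitatively: *which cardiac
properties carry the most leverage for maintaining the ejection fraction
(EF), and how does that leverage shift as the wall hypertrophies?*  This
note documents the model, its assumptions, the numerical choices, and what
the synthetic data do and do not emulate.

## The model

### Anatomy

The LV is a thick-walled semi-ellipsoid of revolution: endocardial semi-axes
(cavity length `L`, equatorial radius `R`), epicardial semi-axes offset by
the wall thickness `LVWT`.  Material points sit on a transmural × meridional
grid (`n_layers` = 4 × `n_segments` = 24 by default; the nested-shell
volumes agree with the closed forms to <0.1% from 4×16 up).  Myofibers lie
in the wall-tangent plane at an elevation angle that varies linearly across
the wall (default +50° endocardium → −50° epicardium, as measured by
diffusion-tensor imaging in rat); the imbrication angle is fixed at zero.
The canonical configuration used throughout the sensitivity analysis is
`L` = 10 mm, reference diameter 3 mm, `LVWT` free.

### Passive tissue

Transverse-isotropic exponential strain energy in fiber–sheet–normal axes,

    W = (c1/2)(e^Q − 1),
    Q = c2·E11² + c3·(E22² + E33² + 2E23²) + 2c4·(E12² + E13²),

with `c2` = 8.0, `c3` = 2.0, `c4` = 3.7 (rodent data) and the prefactor
`c1` free.  The `(e^Q − 1)` convention makes the reference state stress-free
with zero energy.  Because the end-diastolic pressure is assumed rather than
measured, the fitted stiffness is reported as `c̃₁ = c1/p_ed` with
`p_ed` = 1 kPa.  Note that on the canonical geometry the tiny reference
cavity must inflate several-fold to reach a physiologic end-diastolic
diameter, so fitted `c1` values are extremely small numbers — the quantity
is identified logarithmically through the exponential law, which is also why
the Newton fitter works in log-parameter space.

### Reduced kinematics

The full 3-D finite-element problem is replaced by a Rayleigh–Ritz family
with three generalized coordinates: cavity volume `V`, endocardial apex–base
extension ratio `a` (exposed as `lambda_z`), and a transmural axial-slope
coordinate `b`.  Shell `ξ` of the wall maps to a semi-ellipsoidal shell with
axial semi-axis `a·L + b·ξ·LVWT`; its equatorial radius is fixed by exact
conservation of the tissue volume enclosed inside it, and material points
slide in the meridional angle so that the volume between any two material
cones is also conserved.  The map is therefore pointwise incompressible
(λ_c·λ_m·λ_t = 1 with λ_t the true thickness stretch), and for a spherical
reference it contains the exact incompressible-inflation field in the
thin-wall limit: against the closed-form thick-sphere solution the inflation
pressure agrees to ~1.3% at `t/R` = 0.05.  The two shape coordinates were
both found necessary: with a single axial coordinate the family either
develops a spurious oblate soft mode or cannot nest its shells at large
inflation.  A twist coordinate is scaffolded but disabled by default, since
torsion showed no systematic SHAM/AB trend in the underlying measurements.

Equilibrium is the stationary point of the total potential over (`a`, `b`)
at imposed `V` (or over all three at imposed pressure), solved by a damped
Newton iteration on the analytic gradient with a coarse-scan/L-BFGS fallback
for cold starts.  Active tension enters as a fiber-aligned Cauchy stress
`T_a·(f⊗f)` whose virtual work is `∫ (T_a/λ_f) δλ_f dV0`; the solver
receives the tension *model* (a callable of the fiber-stretch field) so its
iteration sees the stabilizing slope of the length dependence.  The entire
state evaluation is numba-compiled; one evaluation costs ~35 µs.

### Excitation–contraction

A spatially uniform calcium transient drives two first-order Hill stages:
troponin-C occupancy (`n_trpn` = 2, `k_trpn` = 0.1 /ms, half-activation
`Ca50` free) and a two-state crossbridge cycle (`n_xb` = 5,
`k_xb` = 0.02 /ms, `TRPN50` = 0.35).  Active tension is
`T_a = T_ref·g·h(λ)·f_xb` with `T_ref` = 120 kPa.

The length dependence `h(λ) = max(0, 1 + 4.9(λ−1))` operates on a sarcomere
extension ratio, not on raw tissue stretch: the canonical reference cavity
inflates so far that fiber stretches relative to the mesh reach ~2.8, far
outside any sarcomere operating range.  The organ–cell coupling is

    λ_cell = λ_sarc,ED · (1 + κ·(λ_f/λ_f,ED − 1)),  clipped to [0.61, 1.2],

with `λ_sarc,ED` = 1.1 (end-diastolic sarcomeres sit ~10% above slack on the
ascending limb) and an attenuation `κ` = 0.55 reflecting that this family's
fiber-stretch excursions over a beat are far larger than in-vivo sarcomere
excursions.  These two constants were fixed once, by requiring that the
study's operating window (EF 65–85% at p_max 12–20 kPa) be attainable with
smooth EF control on the canonical LVWT = 2 mm geometry; they are exposed on
`LVModel` for exploration.

The velocity dependence is a single-exponential fading-memory kernel
`dQ/dt = −α·Q + A·dλ_cell/dt` (α = 0.1 /ms) with gain
`g = (1+aQ)/(1−Q)` for shortening and `(1+(2+a)Q)/(1+Q)` for stretch
(a = 0.35, clipped at zero).  The kernel integrates the *sarcomere* strain
rate and `A` = 4.0, chosen so the force–velocity depression at physiological
ejection rates is moderate (g ≈ 0.8–0.95); much stronger damping (A ≈ 25,
full Hill-scale depression) over-damps ejection and pushes the attainable
EF below the study's range.  A `velocity_dependence = False` switch isolates
velocity effects.

### Circulation and cycle protocol

Ejection couples to a three-element Windkessel (aortic impedance
`z` = 6.3 mmHg·s/ml, peripheral resistance `r` = 105 mmHg·s/ml, compliance
`c` = 0.014 ml/mmHg); aortic banding raises `z` by 50% to 9.5 mmHg·s/ml.
Internally everything runs in (kPa, µl, ms); conversions live in one module
and are round-trip tested.

Each beat runs four phases: quasi-static filling to `p_ed` = 1 kPa;
isovolumetric contraction until the LV pressure reaches the free
valve-opening pressure `p_a` (the arterial state is re-initialized to `p_a`
at each opening — with the valve closed, the diastolic arterial run-down
cannot feed back on the LV); Windkessel-governed ejection until volume flow
reverses; isovolumetric relaxation back to `p_ed`.  Beats are event-driven:
the calcium clock restarts at contraction onset and the nominal 200 ms
period is a *minimum* beat length.  This matters because the printed
crossbridge off-rate (0.02 /ms) implies a ~50 ms tension tail, so relaxation
plus diastole can exceed 200 ms; diastole simply extends until residual
activation is negligible, which also pins the end-diastolic state to the
passive inflation state.  Since filling is quasi-static, the phenotypes are
insensitive to the diastolic interval.  Valve-opening and flow-reversal
instants are interpolated inside the time step so that phenotypes are smooth
functions of parameters (needed by the Newton fitter and by the central
differences of the sensitivity analysis).  Beats repeat until EDV and ESV
change by <1e-4 relative between beats (typically 3–5 beats; one limit
cycle costs ~2–8 s).

### Fitting and sensitivity

Three free parameters (`c̃₁`, `p_a`, `Ca50`) are fitted to a phenotype
triple (LVEDD, p_max, EF) by damped Newton iteration in log-parameter space
(positivity for free; relative steps natural for the log-identified `c̃₁`),
forward-difference Jacobian with log-step 0.05 (wide enough to dominate the
simulator's ~1e-3 event-timing noise floor in EF), step-halving damping, and
a 1% default tolerance on the largest relative phenotype residual.  The
start point is physics-anchored: `c1` from the passive inflation that
reaches the target LVEDD exactly (passive pressure is strictly proportional
to `c1`), `p_a` at 45% of the target p_max, and `Ca50` from a four-point
activation pre-scan log-interpolated to the target EF (the EF–Ca50 relation
shifts strongly with wall thickness).  Fits typically converge in 2–5
iterations, echoing the underlying study's 1–2.

The compensatory ability of a parameter `u` is the span-scaled sensitivity

    S[EF, u] = ∂EF/∂u · (u_AB − u_SHAM) / EF,

a central difference of full limit-cycle simulations at step 1% of the span,
without refitting (S is a partial derivative).  Default spans anchor to the
measured/fitted SHAM→AB differences: +1.0 mm for LVWT, −0.6 µM for PCa,
−0.71 µM for Ca50.  S is signed — the AB−SHAM span of PCa is negative while
EF rises with PCa, so S[EF, PCa] < 0 — and trend comparisons across wall
thickness use the magnitudes |S|, which is how compensatory ability is
interpreted.  Along SHAM→AB trajectories (`trajectory_scan`) the geometry
and fibers are interpolated through the generalized coordinates `u_geom`,
`u_fiber`, phenotype targets are interpolated linearly, and the free
parameters are refitted at each interior state.

## Synthetic data

No measurement from the underlying study is public, so the package
generates every input it needs.

**Calcium transients** are a half-cosine rise (default time-to-peak 20 ms)
followed by an exponential decay (τ = 50 ms) renormalized to close the
200 ms period, with extrema exactly at the configured (DCa, PCa).  Peaks
use the measured cell values, 1.53 µM (SHAM) and 0.93 µM (banded);
diastolic levels are not reported and default to 0.10/0.12 µM (typical
resting myocyte).  Hybrid traces blend two affinely normalized waveforms
and rescale to convex-combined levels, which is how the sensitivity
analysis realizes arbitrary (DCa, PCa).

**Echo cohorts** emulate longitudinal M-mode recordings: per rat, a true
diastolic geometry, a target EF, and a weekly relative wall-growth rate are
drawn from cohort distributions whose defaults are the study statistics —
SHAM EF 0.75 ± 0.05 with growth 0.03 ± 0.02 /week, banded EF 0.71 ± 0.06
with growth 0.095 ± 0.030 /week, n = 10, visits at weeks 0/2/4.  Baseline
diameters anchor to the measured hearts (8.1/7.9 mm); baseline wall
thickness (1.6/1.7 ± 0.15 mm), base–apex shortening fraction (0.15),
measurement noise (0.05 mm per sample per wall), six beats per recording
and the 200 ms period are package choices at typical rat values.  Within a
beat the walls follow a raised cosine between diastole and systole; the
systolic inner radius is chosen so that the cylindrical-slice EF — with the
slice height shortening by the base–apex fraction and the annular tissue
volume conserved — equals the drawn EF exactly, and the systolic thickness
follows from the same conservation at every sample.  What this does *not*
emulate: ultrasound physics (speckle, dropout), beat-to-beat variability,
respiratory motion, probe-angle error, or any real-image segmentation; a
passing round-trip therefore shows estimator correctness on clean
wall-position data, not robustness to real echocardiograms.

**M-mode analysis** detects beats as peaks of the inner-diameter signal
(minimum separation half the nominal period), takes within-beat extrema for
diastolic/systolic values, and averages over beats.  Traces are smoothed
with a Savitzky–Golay filter (polyorder 2, 31 ms window) first — exact on
locally quadratic extrema, so the noiseless round trip is preserved while
per-sample noise cannot bias the within-beat maxima.  The EF estimator uses
the tissue-volume-conserving cylindrical-slice formula; the variant with the
diastolic radius in the final denominator term, which appears in print but
contradicts the conservation argument it comes from, is retained behind
`formula="printed"`.  The normalized remodeling rate `R[y]` is the ordinary
least-squares slope over the visits divided by the baseline value, and group
comparisons use Welch's two-sided t-test (unequal variances are evident in
the cohort spreads).

## Numerical choices

- Exponent guard: `Q` is clipped at 600 (float64 overflows at ~709); fitted
  states sit far below the clip.
- Shape solves: analytic-gradient damped Newton, Jacobian refreshed when
  progress is slower than quadratic, tolerance max(1e-8·energy-scale,
  1e-6·stiffness) ≈ coordinate precision 1e-6; coarse geometric scan +
  bounded L-BFGS fallback on cold starts, with minimum-potential root
  selection among coexisting equilibria.
- Volume-at-pressure solves: warm Newton on `V`, falling back to a bracket
  walk with bisection (the warm-started pressure evaluation is slightly
  path-dependent, which Brent's method does not tolerate).
- Time steps: 0.5 ms systole, 1 ms relaxation, 2 ms filling; ejection uses
  an adaptive step (halved while the predicted flow change is too large,
  floored at dt/8) with the onset/reversal events interpolated.
- Ejection is floored at 10% of EDV: below that the reduced family
  approaches collapse, and every target of interest lies well above it.
- Degenerate inputs: flat traces raise insufficient-data errors; non-physical
  cohort draws are redrawn with a capped retry count; a ventricle that never
  reaches `p_a` returns a stalled loop flagged with EF = 0 (mirroring the
  discarded failed-ejection hearts), rather than raising.

## Problem sizes

The default suite and the acceptance script run at desk scale: 10-rat
cohorts, single fits on the canonical geometry, and the wall-thickness trend
check at 3 thicknesses × 2 target triples with the {2.0, 2.5, 3.0} mm grid.
That grid reflects a known limitation (below): at `LVWT` ≲ 1.5 mm this
reduced model cannot reach EF 75% against a 16 kPa afterload, so thinner
grid points would be recorded as unattained gaps.

## Known limitations

- The kinematic family is axisymmetric with three global coordinates; it
  cannot represent azimuthal asymmetry, local wall-motion abnormalities, or
  transmurally varying axial stretch beyond a linear profile.  Wall-volume
  conservation and pointwise incompressibility are exact in-family, but the
  family itself is a Ritz restriction of the true mechanics.
- Tension capacity at thin walls: with the fixed sarcomere coupling
  (κ = 0.55, λ_sarc,ED = 1.1) the peak isovolumetric pressure at
  `LVWT` = 1 mm is ~11 kPa, so phenotype triples demanding EF 75% at
  p_max 16 kPa are unattainable below ~2 mm wall thickness; such sweep
  points are reported as gaps, not errors.
- The fitted `c̃₁` on canonical geometry is identified only logarithmically
  (the exponential law pins LVEDD almost independently of `c1` scale); its
  absolute value should not be compared across geometries.
- Because the ejection-pressure maximum is tension-capacity-driven in this
  family, the calcium sensitivity carries most of the p_max response and the
  fitted valve-opening pressures sit low (a few kPa).  The systolic pair
  (`p_a`, `Ca50`) is jointly identifiable (well-conditioned submatrix) but
  has a sloppy direction: compensating shifts of roughly −4% in `p_a` and
  +2% in `Ca50` move all three phenotypes by under 0.2%, so individual
  recovery of `p_a` from data is limited to the few-percent level at
  realistic phenotype precision.  A longer calcium decay (τ = 90 ms) was
  evaluated as a remedy and rejected: it barely moved the fitted `p_a`
  while degrading the wall-thickness sweep behavior.
- Cell kinetics use the simplest saturating Hill forms consistent with the
  published coefficients; no ionic electrophysiology, no metabolite
  accounting, and the relaxation tail is set entirely by the crossbridge
  off-rate.
- The Windkessel has no valve inertia or regurgitation and no venous return
  model; the arterial state is re-initialized at each valve opening, so
  beat-to-beat arterial memory is deliberately absent.
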