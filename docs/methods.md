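# Methods

`paleosoar` quantifies the two soaring styles available to large flyers —
thermal soaring and dynamic soaring — from nothing but a species'
morphology (mass m, wingspan b, wing area S_W) and a small set of
aerodynamic coefficients, and applies the machinery to four extinct giants
(*Pelagornis sandersi*, *Argentavis magnificens*, *Pteranodon*,
*Quetzalcoatlus*), nine extant reference birds, and one motor glider.

## Aerodynamic model

The animal is a point mass under gravity, lift L = ½ρ C_L S_W V², and drag

    D = ½ρ S_W V² [ C_Dpro(C_L) + 0.01 + k C_L² / (π R_a) ],

with aspect ratio R_a = b²/S_W and induced-drag factor k = 1.1.  The
profile-drag coefficient follows the measured parabola
C_Dpro = C_Dpro,min + k_pro (C_L − C_L,Dpro,min)²; the coefficient sets are
(0.019, 0.030, 0.77) for birds (wind-tunnel jackdaw glide) and
(0.050, 0.11, 1.0) / (0.077, 0.065, 0.89) for faired / unfaired
reconstructed pterosaur membrane wings.  Parasite drag is folded into the
wing term as C_Dpar S_B = 0.01 S_W because neither factor is known
separately for these animals.  Maximum lift coefficients: 1.8 (birds),
2.0 (pterosaurs, whose membranes reach higher C_L), 1.3 (ASK-14 envelope).
Air density defaults to 1.23 kg/m³ (sea-level ISA); a 1.48 kg/m³
high-oxygen scenario is the sensitivity case.  g = 9.81 m/s² throughout —
it reproduces every self-consistent published wing loading.

Two wingspan rules at speed: birds flex their wings, shrinking b, S_W, and
R_a by β(V) = (B_stop − V/V_s)/(B_stop − 1) with B_stop = 5 (V_s is the
stall speed √(2mg/(ρ S_W C_Lmax))); pterosaur membranes are kept at fixed
span (no mechanism is known that shortens a membrane wing without slack),
with B_stop = 6 available as the alternative configuration.

## Thermal stage

The straight-glide polar is the equilibrium sink rate

    V_sink(V) = ½ρ (S_W/mg)(β C_Dpro + 0.01) V³ + (mg/S_W)(2k/(ρ R_a β² π)) / V,

with C_L = 2mg/(ρ β S_W V²) substituted into the profile-drag parabola; the
parasite term deliberately uses the unreduced S_W.  The maximum glide ratio
max √(V² − V_sink²)/V_sink is found by bounded scalar search over
[V_s, V_hi] (V_hi: the speed where β reaches its 0.05 numerical floor for
flexing wings, 4 V_s for fixed span, 60 m/s for the glider) and is verified
against a dense-grid oracle (ΔV = 0.01 m/s) in the tests.  The ASK-14 rows
bypass the model entirely and evaluate its measured polar
V_sink = 10/V + 5.2·10⁻⁵ V³; note the polar-derived best ratio is ≈ 21.9.

Circling at bank φ and lift coefficient C_L* maps the straight-glide state
onto a circle: r = V(C_L*)²/(g sin φ), V_sink,circle = V_sink(C_L*)/(cos φ)^{3/2}.
V(C_L*) solves V² β(V) = 2mg/(ρ S_W C_L*) by bisection on the slow branch
[V_s, (2/3)B_stop V_s] (closed form for fixed span).  Two envelope
definitions are computed:

* **optimal** — for each radius, minimize over C_L* ≤ C_Lmax and φ subject
  to the radius constraint (a coarse C_L* scan plus a bounded polish; a
  400-point 2-D grid oracle checks it in the tests).  Its smallest radius is
  the limiting radius V_s²/g.
* **parametric** — fix C_L* (at the minimum-sink value, or at C_Lmax for
  the headline envelope tables) and sweep φ.  The optimal envelope
  dominates this one pointwise by construction.

Headline envelope tables cap the bank at 40°; the full curve is computable
to 89.9°.  Radii are reported log-spaced from 1.05× the capped limiting
radius to 10⁴ m.  Two scaling laws follow from the algebra and are asserted
on synthetic morphologies: minimum sink ∝ (wing loading)^½ (fixed span,
frozen profile drag) and circle radius ∝ wing loading at fixed φ and C_L*.

## Dynamic stage

In a steady horizontal wind W(z) along −y, the point-mass equations of
motion in airspeed V, pitch γ (positive nose-down), yaw ψ, and bank φ
contain the shear term ∂W/∂z · dz/dt, the only energy source of the cycle.
Two shear profiles are used: logarithmic
W(z) = W₁₀ ln(z/h_min)/ln(10/h_min) with roughness height h_min = 0.03 m,
and sigmoidal W(z) = W_max / (1 + e^{−(z−h_w)/δ}) with shear heights
h_w ∈ {1, 3, 5} m and thickness parameter δ ∈ {3/6, 7/6} m — seven
conditions in all.  The lift coefficient is one cycle-constant decision
variable; bank is the time-varying control.  The wing is unreduced in this
stage: span adjustment is a gliding-performance construct, and the wingtip
constraint uses the full span b.

The periodic optimal-control problem — periodicity in (z, γ, ψ, φ, V),
load factor L/mg ≤ 3, wingtip clearance z − (b/2)|sin φ| cos γ ≥ 0
(implemented as the equivalent smooth pair z ∓ (b/2) sin φ cos γ ≥ 0),
z ≥ 0.5 m — is transcribed by trapezoidal collocation on N = 51 nodes with
free cycle period τ: 7 per-node variables plus C_L and τ (plus the wind
parameter when it is the objective) give 359 or 360 variables; equalities
are the 6(N−1) = 300 trapezoidal defects, the start anchor x₁ = y₁ = 0, and
the five periodicity conditions.  Scaling: positions /100 m, speeds
/20 m/s, τ /10 s.  Bounds: V ∈ [2, 80] m/s, γ ∈ ±80°, φ ∈ ±85°,
ψ ∈ [−3π, 3π] (literal ψ₁ = ψ_N periodicity, excluding net-rotation loops),
τ ∈ [1, 60] s, z ∈ [0.5, 100] m, wind parameter ∈ [0, 40] m/s.

Objectives: minimize the wind-profile parameter (W₁₀ or W_max) sustaining a
cycle; maximize cycle-averaged travel speed √(x_N² + y_N²)/τ; maximize
upwind speed y_N/τ.  The NLP is solved with SLSQP.  All constraint
Jacobians are exact to machine precision via batched complex-step
differentiation (step 10⁻¹⁰⁰), which is what makes the dense SQP practical
at this size; objective gradients are analytic.

Initial guesses are inclined elliptical loops (centre height just above the
shear layer, airspeed 1.6 V_s, period ≈ 6 s scaled by V_s/11, randomized
amplitude/heading/bank phases).  Cold starts are first converged on a
coarse 21-node mesh (failed coarse attempts are cheap and discarded; up to
three per requested start are drawn), the distinct coarse optima are
interpolated onto the working mesh and polished; stalled SLSQP runs are
restarted from their incumbent up to twice.  A solution is accepted at
scaled feasibility ≤ 10⁻⁶; if no start converges, an infeasibility marker
is returned — with the 40 m/s wind-parameter bound this is the model's
statement that no periodic cycle exists at any admissible wind
(it occurs only for the giant species under surface-hugging shear).
Identical problem objects and seeds reproduce solutions bit-for-bit.

The wind-speed sweep solves the minimum wind per species, then the two
speed objectives on a grid from each species' own minimum to the largest
minimum across the set + 2 m/s (default step 0.5 m/s), warm-starting each
solve from the neighbouring wind; the travel series stops after the first
wind where it exceeds 40 m/s.

### Diagnostics

Every accepted cycle carries an energy audit: along the cycle
d/dt(V²/2 + gz) = −DV/m + W′(z) ż V cos γ sin ψ, so with V and z periodic
the integrated drag work must equal the integrated shear extraction; the
audit integrates both sides with the same trapezoidal rule and the tests
require agreement within 1% (in practice the residual is ~10⁻¹⁰, because
the defect constraints couple the two quadratures).

## Synthetic data and fixtures

`gen_morphologies` samples mass log-uniformly over [1, 300] kg (mirroring
the petrel-to-pterosaur spread), wing loading uniformly over
[30, 250] N/m², aspect ratio uniformly over [5, 18], and derives
S_W = mg/loading, b = √(R_a S_W); a biased coin assigns the pterosaur
group.  All randomness flows from one seeded generator (default seed
20220310).

`gen_fixture_trajectories` builds exact still-air solutions: the
equilibrium straight glide (tan γ = C_D/C_L) and steady helical descents at
15/30/45° bank (tan γ = C_D/(C_L cos φ), uniform turn rate), each sampled on
the collocation nodes.  These give machine-zero EOM residuals everywhere;
the glide — linear in time — also gives machine-zero trapezoidal defects,
while the curved helix leaves the trapezoidal quadrature error, which the
tests verify shrinks at third order in the step.  What the synthetic layer
does not emulate: gusts or unsteady wind, morphological measurement error,
and flapping — so passing tests validate the optimization and algebra, not
the fidelity of steady-wind assumptions to real seas.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run every transcription at the
study's N = 51 (the mesh-refinement check compares against N = 101), but
use 2–4 multistarts per solve with warm-start chaining across neighbouring
wind conditions and species rather than the full 8-start default; the
multistart default remains 8 for standalone use.  The species-ordering
checks cover all seven wind conditions.  The analysis drivers default to a
3-condition subset (`--all-conditions` restores the full grid).

## Known limitations and discrepancies

* Two rows of the published morphology table are internally inconsistent
  (Quetzalcoatlus wing loading 224 vs 222.9 recomputed; black-browed
  albatross 87.5 vs 92.6; the white stork wingspan is inconsistent with its
  own area and aspect ratio and is back-derived as 2.00 m).  The registry
  stores the printed raw values (with the stork span correction) and the
  tests pin the recomputed columns.
* The ASK-14's printed polar yields a best glide ratio of ≈ 21.9, not the
  "nearly 30" sometimes quoted for the airframe; the polar-derived value is
  reported.
* Under the logarithmic profile the wingtip constraint is *not* neutral
  even for the smallest bird (removing it lowers the petrel's minimum wind
  by ≈ 9%), because that profile concentrates its gradient at the surface;
  the near-neutrality of the constraint for small species holds for shear
  layers lifted above the surface (sigmoidal h_w = 3 m: < 2% change).
* Minimum-wind optima are local (SQP from randomized starts); the shipped
  multistart settings reproduce a consistent basin across seeds, but a
  globally better cycle can never be ruled out.
* Under the logarithmic profile no admissible cycle exists for
  Quetzalcoatlus within the 40 m/s wind bound (nor at 80 m/s in a probe
  run); its dynamic-soaring requirement there is reported as "above the
  bound" rather than as a number.
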