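# Methods

## Model and construction

We consider two diffusible populations ("morphogens") u(x, t), v(x, t) on
an interval [0, L] or rectangle [0, Lx] × [0, Ly] with zero-flux
boundaries:

    u_t = ∇²u + f(u, v),        v_t = D ∇²v + g(u, v),

in nondimensional units where the diffusivity of u is 1 and D = Dv/Du.
A homogeneous steady state (U, V) with f = g = 0 undergoes a Turing
(diffusion-driven) instability when it is stable without diffusion
(tr J < 0, det J > 0 for the Jacobian J at the steady state) but some
finite wavenumber grows with diffusion on.  Writing the admissible sign
structures as *pure* (+,−; +,−) or *cross* (+,+; −,−) and reducing by the
magnitudes F = |g_u||f_v|/f_u², G = |g_v|/f_u (time in units of 1/f_u,
length in units of √(Du/f_u)), the instability conditions collapse to

    F > G > 1   and   D > D_c = (√(F−G) + √F)².

The unstable squared wavenumbers are the roots of
D k⁴ − (D−G) k² + (F−G) = 0, and on a 1D zero-flux domain the admissible
modes are k = nπ/L, so the smallest patterning domain is L_c = π/k₊.

The design inverse problem is solved by prescribing the Jacobian.  For a
user-chosen level-set function S(p) we set F = S + 2 and G = 2 (i.e.
F′ = F−1 = S+1, G′ = G−1 = 1, with the offset fixed at 1 to keep g's
constant term positive), so det J = F − G = S and the Turing space is
exactly Ω = {S > 0}.  The kinetics are the lowest-order polynomials
satisfying the constraint system {f(U,V) = g(U,V) = 0, prescribed J} on
the ansatz

    cross:  f = a₁ + b₁ u + c₁ u^α v,     g = a₂ + b₂ v + c₂ u v,
    pure:   f = a₁ + b₁ u^α + c₁ u v,     g = a₂ + b₂ v + c₂ u v,

with α = 2 by default (the smallest exponent keeping a₁ ≥ 0; larger α is
accepted and the coefficients re-solved).  At (U, V) = (1, 1) this gives
the familiar f = −u + u²v (cross) and f = u² − uv (pure).  Every
constructor output is re-checked numerically (`verify_kinetics`): steady
state residuals < 1e−10 and a central-difference Jacobian matching the
analytic one.  Where several printed variants of these systems circulate
with inconsistent signs, the constraint system is treated as the source
of truth; it reproduces all the anchor numbers below.

Additional families:

- `build_phase_switching(a, b)` realizes the two-branch region
  (a−3)² − b² ≥ 1 (a, b > 0) with Jacobian [[1, a−3], [3−a, −b²−1]]:
  pure (in-phase) for a < 3, cross (out-of-phase) for a > 3.  At a = 3
  the u²v saturation vanishes and solutions blow up in finite time; the
  constructor refuses a = 3 unless overridden or given the optional
  saturating guard u² → u²/(1+ε²u²) (which perturbs the steady state and
  Jacobian at O(ε²); the verification report records that drift).
- `build_at_steady_state(U, V, S)` places the cross family at an
  arbitrary positive steady state, with coefficients a₁ = V−U, a₂ = 2V,
  b₁ = (U−2V)/U, b₂ = (SU+2U−2V)/V, c₁ = U⁻², c₂ = −(S+2)/V.  U and V
  may be arrays (heterogeneous target states); positivity of trajectories
  is then only monitored, not guaranteed.
- `build_circle(a, b)` is the disc worked example with the direct
  parameterization F = 2 − a², G = 1 + b².  It uses the cross
  construction: the pure variant f = u² − uv admits finite-time blow-up
  outside the disc (once the saddle at (1,1) sends v low, u′ ≈ u² wins),
  whereas the cross form decays in u there.  Out-of-phase patterns
  follow.
- `with_cubic(sys, C)` subtracts C(u−U)³ from f.  The term has zero
  value and slope at the steady state, so the linear analysis is
  invariant; its role is nonlinear wavemode selection — quadratic-
  dominated kinetics favour spots, cubic-dominated favour
  stripes/labyrinths.  C < 0 is rejected (it would promote blow-up).

Coefficients are kept as exact rationals when the inputs are rational,
and all coefficient formulas broadcast over numpy arrays, which is how
spatial heterogeneity enters: a parameter field simply produces
node-wise coefficient fields.

## Region analysis

Suprema of D_c, L_c, F or S over the closed region {S ≥ 0} ∩ box are
computed by a dense grid scan (default 401 points per axis over the
bounding box) followed by six rounds of local grid zooming around the
incumbent maximum.  This is deterministic for a fixed resolution and
treats the region as a black box, which is the right trade-off for
user-defined level sets; the default resolves the disc anchors to well
below 1e−4.  `recommend_D_and_L` returns both the sharp bound
sup D_c and the cruder always-sufficient rule D = 4·sup F
(= 4(2 + sup S) for the canonical family), plus sup L_c at the working D.

Anchor values (disc, F = 2−a², G = 1+b²): sup D_c = (1+√2)² ≈ 5.8284 at
the origin; conservative D = 8; sup L_c at D = 8 is
4π/√(7+√17) ≈ 3.77.  Two-branch region restricted to 0 ≤ a ≤ 6:
sup D_c = 17 + 12√2 ≈ 33.97, so D = 50 suffices.

Inequalities within 1e−9 (relative) of equality are flagged `marginal`
and never silently rounded.  The G = 1 boundary (b = 0 in the disc
example) makes the uniform mode a linear centre (tr J = 0); we follow
the worked examples in proceeding anyway, flagged.

## Simulation protocol

Space: second-order central differences with mirror (zero-flux) closure;
1D 3-point / 2D 5-point stencils assembled sparsely.  Time: SciPy's BDF
with the analytically assembled sparse Jacobian (diffusion blocks plus
node-diagonal reaction partials), rtol 1e−5 / atol 1e−8 — A(α)-stable
for the stiff diffusion part with local error control.  Initial
conditions are uniform random perturbations about the (possibly
heterogeneous) steady state with *total* width `ic_range` = 0.1 by
default, i.e. ±0.05; we read "range" as total spread, and a half-width
interpretation is available as a config switch (classification outcomes
are insensitive at this amplitude).  A run is converged when
sup|∂u/∂t|, sup|∂v/∂t| < 1e−3 *and* t ≥ t_min (default 1e4), checked at
t_min and then at doublings; a hard cap (default 5e4) returns
`converged=False` rather than raising.  Runs whose residual has stopped
decaying while the spatial amplitude is unchanged are reported
`oscillatory` — on the trace-zero boundary the uniform mode can ring for
a long time and this flag distinguishes a breathing-but-patterned state
from non-convergence.  Blow-up (any |field| > 1e6 or non-finite) raises
`BlowUpError` with the failure time; polar sweeps record it per cell and
continue.

Piecewise-constant time schedules (square-wave parameter switching,
H(cos 2πt/period), switches at period/4 + k·period/2) are honoured by
restarting the integrator at every switch time and capping the step at
`dt_max` = 10 within scheduled epochs.  Mesh adequacy is checked the
same way the patterns are validated: `refine_check` re-runs at half the
mesh size with the same coarse-grid noise (linearly injected) and
compares classifications.

Default resolutions aim at ≥ 8 nodes per predicted pattern wavelength
2π/k_max.  The shipped tests use 256 nodes for 1D runs and 64²–128² for
2D 50×50 domains with t_min between 800 and 2000 for the 2D suites —
patterns establish by t ≈ 300–500 at these growth rates, and the same
convergence rule still applies; the 1D bifurcation experiment keeps the
full t ≥ 1e4 protocol.

## Pattern classification

The classifier is a declared convention validated on constructed inputs,
not a reconstruction of anyone's visual judgement:

- homogeneous: amplitude (max − min of u) < `het_tol` = 0.05 — pattern
  amplitudes here are O(1) while linear decay residuals are far smaller;
- 1D mode count: sign changes of u − mean(u), ignoring excursions below
  10% of the half-amplitude, so cos(nπx/L) counts n and a half-cosine
  boundary peak counts as mode one;
- 2D spots vs stripes: threshold at the mean, 8-connected components of
  the high phase, isoperimetric circularity 4πA/P² per component
  (Crofton perimeter).  Median circularity ≥ 0.6 with no
  domain-spanning component → spots; median < 0.4 or a spanning/
  over-elongated component → stripes; otherwise mixed (stripe regimes
  do sometimes degenerate into spot-like fragments);
- phase: Pearson correlation of the two fields, ±0.5 threshold,
  indeterminate for near-homogeneous fields;
- per-segment reports clip components at segment boundaries so mixed
  prepattern simulations can be judged region by region; segments
  smaller than 64 pixels are flagged low-confidence.

All thresholds are keyword-configurable; the defaults are what the test
suite validates.

## Heterogeneity and images

Spatial steps are smoothed tanh profiles (default width one coordinate
unit) to avoid stencil artefacts at jumps.  Grayscale images (PNG/PGM)
are segmented by intensity thresholds (defaults: k-quantiles; label 0 =
brightest) and mapped per label to parameter values; a second pathway
scales the steady state U(x) linearly and inversely with intensity
(white → low, black → high).  Image row 0 (top) maps to y = Ly when
`flip_rows` is set.  Only synthetic, programmatically generated fixture
images ship with the tests (`make_fixture_image`); real photographs and
their contrast handling are out of scope, so the presets reproduce the
per-region parameter values on synthetic fixtures only.

## What the tests do and do not show

The synthetic experiments are exactly the study conditions of the worked
examples: small uniform noise around a designed steady state, ideal
polynomial kinetics, rectangular domains.  Passing them shows the
construction places the instability region, phase and pattern type where
intended under those conditions.  It does not show robustness to
non-polynomial kinetics, stochastic (low-copy-number) dynamics, growth
or curved geometry, all of which are out of scope.

Known limitations:

- Outside Ω nothing is constrained by design; the disc worked example
  genuinely blows up there in finite time (recorded honestly as
  `blowup`), and phase-switching kinetics blow up at a = 3.
- For heterogeneous steady states, (U(x), V) is not an exact steady
  solution once diffusion acts across gradients; the construction is
  asymptotic in the heterogeneity length scale.  With S < 0 the local
  uniform state is a saddle, so "preserving" a prepattern there relies
  on the large-C cubic pinning, a nonlinear effect we demonstrate but do
  not analyse.
- The spot/stripe classifier is threshold-based; patterns near the
  spot–labyrinth crossover may legitimately classify as mixed.
- Trajectory positivity is monitored (`positivity_ok`), not proven, for
  steady states away from (1, 1).
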