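# Methods

This note documents the models implemented in `plmotion`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish.

## Pendulum kinematics

The reference stimulus is the bob of a virtual simple pendulum,
θ̈ = −(g/L)·sin θ, released from rest at θ₀ = π/4 with L = 0.64823 m and
g = 9.81 m s⁻² (amplitude A = 2θ₀ = π/2).  The equation of motion is
integrated with fixed-step fourth-order Runge-Kutta at 10 kHz — the grid on
which display position sequences are generated — and the period is measured
from linearly interpolated same-direction zero crossings of the angular
velocity.  The closed-form period 4·√(L/g)·K(sin(θ₀/2)) (complete elliptic
integral of the first kind) serves only as a scalar constant and test
oracle; the motion itself always comes from the integrator.  At these
settings the specific energy ½Lω² − g·cos θ is conserved to better than
10⁻⁶ (relative) over a period, and the measured period agrees with the
closed form to 10⁻⁴ relative.

**Frame-quantized design period.**  The exact period is 1.67970 s, but the
display runs at 100 Hz and sweeps must span whole frames, so all profile
grids use the *design* period 1.68 s (840 ms per half-period sweep, 16 800
samples per period at 10 kHz).  The pendular speed profile is mapped onto
the design grid by a uniform time rescaling of 0.99982, which preserves the
swept amplitude exactly.

**Harmonic comparator.**  The deviation of the 1g solution from harmonic
motion is computed against θ₀·cos(2πt/T) with equal amplitude and the
design period T = 1.68 s (the period the stimulus is actually generated
on); position deviation is normalized by the amplitude θ₀, velocity
deviation by the peak angular speed.  Under this convention the maxima are
0.59 % (position) and 1.34 % (velocity).  Using the raw measured period
instead gives 0.51 % / 1.33 %; the convention is exposed through the
`period` argument of `harmonic_deviation`.

## The 21-profile family

Five basic profiles on the common half-period grid:

* **K₅ (0g)** — constant speed A/(T/2) ≈ 1.870 rad s⁻¹.
* **K₁₀ (1g)** — the unsigned pendulum speed; peak
  √(2(g/L)(1−cos θ₀)) ≈ 2.977 rad s⁻¹ at the trajectory midpoint.
* **K₀ (−1g)** — fastest at the endpoints, slowest at the midpoint.  The
  default construction is the *reflection* of the 1g profile about the
  constant profile, V₋₁g(t) = 2·V₀g − V₁g(t): it conserves the amplitude
  integral by construction and gives K₀ exactly the velocity-change
  magnitude of K₁₀, which is what makes the detectability minima symmetric
  at K₄ and K₆ (~32 % each).  A literal reversed-gravity sweep
  (θ̈ = +(g/L)·sin θ traversing +θ₀ → −θ₀ in T/2, endpoint speed found by
  bisection to 10⁻⁶ s in sweep duration) is available as
  `method="shooting"`; it is a steeper speed law (endpoint 3.23, midpoint
  1.25 rad s⁻¹) and is validated against an independent collocation BVP
  solve in the tests.
* **K₁₅ (2g), K₂₀ (3g)** — zero-endpoint profiles from the two-parameter
  family c·sinᵖ(2πt/T) on [0, T/2]; c is the target peak, fixed by the
  equal-spacing constraints V₂g(T/4) = 2·V₁g(T/4) − V₀g(T/4) and
  V₃g(T/4) = V₂g(T/4) + (V₁g(T/4) − V₀g(T/4)), and p is calibrated by
  root-finding so the amplitude integral equals A on the actual grid.  This
  family has exactly the degrees of freedom the constraints require (zero
  endpoints, symmetry about T/4); profiles built from it carry a
  `family="sin-power"` flag in all exports.

Interpolations: K at index i between lower basic a and upper basic b is
(1−w)·Vₐ + w·V_b with w = (i − iₐ)/5, so K₆ = 0.8·K₅ + 0.2·K₁₀.  This
orientation of the weight makes peak speed monotone in the index over
K₅…K₂₀, matching the ordinal staircase semantics; the mirrored convention
would relabel the interior indices.

**Detectability.**  For each profile, |V₂ − V₁|/V_avg compares the speed at
the sweep endpoint (θ = θ₀) and midpoint (θ = 0) with the segment's mean
speed (path A/2 in time T/4).  At the reference parameters the ratio is 0
for K₅, ~32 % at K₄/K₆, and rises to ~278 % at K₂₀ — all non-constant
profiles sit above the ~25 % acceleration-detection threshold reported in
the literature for comparable stimuli.

## Display geometry

Lengths are placed on screen with the flat-screen rule R = d·tan(α):
viewing distance d = 0.58 m and trajectory radius α = 10.74° give
R = 11.00 cm and arc length R·π/2 = 17.28 cm.  Instantaneous visual angular
velocity is on-screen tangential speed divided by the viewing distance
(small-angle at the display midpoint); the 1g profile peaks at 32.4 ° s⁻¹.
Arc tracks place the trajectory midpoint at the display origin, with the
pivot at distance R opposite the orientation vector (down/left/up for
0°/90°/180°); the occluded-circle condition uses a circle of radius R
centred on the display midpoint, visible in the bottom and top quadrants
(840 ms per quadrant, 3.36 s rotation period).  The nominal angular extents
quoted for the chord (16.51°) and the linear path (17.85°) are not exactly
recoverable from the on-screen lengths under any single visual-angle
convention at this viewing distance; they are carried as metadata, and the
on-screen lengths are authoritative.  No gaze or eccentricity modelling is
attempted: the fixation condition differs from the standard arc only by a
metadata flag.

## Synthetic observers

Participant j in condition c holds a latent prototype with population PSE
μ_c, between-participant shift u_j ~ N(0, τ²) (shared across conditions),
and trial noise σ_c.  A trial draws x ~ N(μ_c + ½ + u_j, σ_c²) and reports
the ordinal index nearest to x (half-down tie rule, clipped to [0, 20]).
The half-index offset makes the ordinal cumulative distribution exactly
P(response ≤ i) = Φ((i − μ_c − u_j)/σ_c), so the probit pipeline estimates
μ_c without discretization bias; its corollaries — a noise-free observer's
responses straddle {μ, μ+1} with the CDF crossing 0.5 at μ, and the mean
response sits at μ + ½ — are asserted in the tests.  Boundary clipping
moves the mean by less than 0.05 index units for μ ∈ [3, 16] and σ ≤ 2.

The procedural mode replays the staircase: the trial target is drawn once,
the observer steps one profile per button press toward it, and a step
requested beyond the range is replaced by a uniformly random member of
{K₆, K₁₀, K₁₄}.  Because stepping toward an in-range target never leaves
the range, the replacement rule (tested directly) is never triggered by
this policy and the endpoint distribution coincides with the direct
sampler's; the adjustment count is the walk minimum |start − response| and
deliberately underestimates the exploratory pressing of human observers (no
mechanism for it is modelled).  An optional linear pull of the target
toward the trial's starting profile is available but off by default.

Defaults are the study conditions: per-orientation PSE (10.08, 9.15, 8.66)
and σ_c = JND_c/Φ⁻¹(0.75) from the published population tables
(1.392/2.051/1.611), τ = 0.5, twelve participants, 5 starts × 10
repetitions per orientation, with no immediate repetition of a starting
profile within a session.

**What the generator does not emulate:** learning or adaptation across
trials, reaction times, eye movements, lapses, or any dependence of σ on
the current profile.  Passing recovery tests therefore show that the
analysis pipeline is unbiased and calibrated *for this generative family*,
not that it would be for human data with structured violations.

## Psychometric pipeline

For each participant × condition and index i ∈ 0…20 the binomial CDF
observation is (successes = #responses ≤ i, size = #trials).  The pooled
probit fit treats the 21 cumulative indicators per trial as independent
binomial observations; they are not independent, so pooled standard errors
are approximate — the delta-method propagation itself is checked against a
10⁵-draw parametric bootstrap (agreement within 5 %).  Whether the original
analyses fitted maximum-likelihood probit to the indicators or least squares
to probit-transformed proportions is not documentable; maximum likelihood is
implemented.

The mixed model places fixed effects on [1, I, D₉₀, D₁₈₀, I·D₉₀, I·D₁₈₀]
and per-participant random coefficients on the same columns.  The marginal
likelihood integrates the random effects by a Laplace approximation around
the per-participant posterior mode (inner Newton iterations, batched across
participants, with analytic first and second derivatives of the
binomial-probit log-likelihood); the outer problem — fixed effects plus log
random-effect SDs — is solved by L-BFGS-B followed by damped Newton polish
on a central-difference Hessian.  That Hessian also supplies the
fixed-effects covariance for Wald statistics and delta-method CIs.  Random
effects default to independent (diagonal) across the six columns: a dozen
participants cannot support a full 6×6 covariance.  One consequence,
verified in the tests, is that switching the dummy reference level is an
exact reparameterization only for coding-independent structures (e.g. the
shared random intercept, invariant to 10⁻³); under the diagonal default the
two codings are nearby but distinct model families and per-condition
PSE/JND move by up to ~10⁻².  Variance components shrinking to the lower
bound (10⁻³) are flagged singular, a warning rather than an error.  An
independent cross-check against lme4's Laplace `glmer` (via Rscript, random
intercept structure) agrees on fixed effects to ~2 %.

PSE and JND per condition compose the intercept and slope across the dummy
coding: PSE = −β₀c/β₁c, JND = Φ⁻¹(0.75)/β₁c, with first-order delta-method
SEs over the relevant covariance block and CIs at ±1.96·SE.  Medians of
even-sized ordinal samples use the standard midpoint convention;
Kolmogorov-Smirnov (asymptotic p) and Kruskal-Wallis are provided for
pipeline reports only.  The rank-based equality-of-variance test mentioned
in the original analyses (Ansari-Bradley) is intentionally not implemented.

## Problem sizes and calibration checks

The recovery study simulates the full three-orientation design (12
participants × 5 starts × 10 repetitions per orientation) 100 times at the
default observer parameters and refits the mixed probit from scratch each
time; the true PSE falls inside its delta-method 95 % CI in ≥ 90 replicates
per orientation, and recovery bias is below 0.1 index units.  Equivalence
checks at τ = 0 reproduce the pooled probit to 10⁻²; the staircase endpoint
distribution matches the direct sampler within total-variation 0.02 at 10⁴
trials.

## Known limitations

* The 2g/3g profiles use the sin-power family defined above; any
  alternative functional form satisfying the same constraints (zero
  endpoints, symmetry, peak spacing, amplitude) would change the
  detectability ratios of K₁₁…K₂₀ by a few percentage points.
* Pooled-probit standard errors inherit the indicator-independence
  approximation; only the mixed model accounts for participant clustering,
  and within-participant dependence across indices remains approximated.
* The printed between-profile peak-velocity difference of 2.1 ° s⁻¹ is not
  reproduced under any single screen-geometry convention tried and is not
  computed by the package.
* The observer model is a measurement model, not a process model: it makes
  no claim about how many button presses a human needs, only where the
  staircase ends.
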