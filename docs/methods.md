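# Methods

## The model

The body above the feet is a single rigid rotation about the ankle in the
sagittal plane.  Its state is the CM angle θ (measured from the anterior
horizontal axis; θ = π/2 with the CM directly above the ankle, θ > π/2
posterior) and the angular velocity ω.  The total external torque about
the ankle — ankle torque τ (positive = plantarflexion) plus gravity
−m g l cos θ — equals d(Iω)/dt.

For the **simple model**, l is constant and I = m l², giving
τ − m g l cos θ = m l² ω̇.  For the **inertia-variable model**, l = l(θ)
and I(θ) = m l(θ)², giving τ − m g l(θ) cos θ = I′(θ) ω² + I(θ) ω̇.
This second equation is *exact*: the angular momentum about a fixed ankle
is L = m l² ω regardless of radial motion, and radial motion is produced
by internal (muscular) forces that exert no moment about the ankle.  No
Lagrangian correction for radial kinetic energy enters, because the
radius is kinematically prescribed by θ, not a free coordinate.

The assumption behind l(θ) is that the joints of the body move in a
stereotyped, synchronized pattern during sit-to-stand, so the CM radius
is a function of the CM angle alone.  The radius function is a cubic
l(θ) = a₀θ³ + a₁θ² + a₃θ + a₄ (the coefficient naming skips a₂), fitted
by OLS to pooled (θ, l) samples from natural trials.  Setting
a₀ = a₁ = a₃ = 0 recovers the simple model, and every operation in the
package reduces exactly to the simple-model result in that limit (tested
to 1e-6 normalized units and better).

## Admissible ankle torque

The foot must not move.  With the foot static, the ground reaction equals
the force transmitted at the ankle: F_x = m ü, F_z = m (ḧ + g), where
(u, h) = (l cos θ, l sin θ) is the ankle-relative CM and

    ü = (l″cosθ − 2l′sinθ − l cosθ) ω² + (l′cosθ − l sinθ) ω̇
    ḧ = (l″sinθ + 2l′cosθ − l sinθ) ω² + (l′sinθ + l cosθ) ω̇

The constraints are:

1. ground contact: F_z > 0;
2. no slip: |F_x| ≤ μ F_z;
3. no tip: the center of pressure from the massless-foot moment balance,
   u_p = (τ − F_x·a)/F_z with a the ankle height, must satisfy
   −d_heel ≤ u_p ≤ d_toe.  (Sanity anchor: in statics u_p = l cos θ, the
   CoP sits directly under the CM.)
4. physiological limits: −τ_df,max ≤ τ ≤ τ_pf,max.

Since ω̇ is affine in τ, every constraint is affine in τ and the
admissible set is a closed interval computed exactly (no scanning).  A
brute-force τ-grid scan that checks the raw constraints (division-form
CoP) is kept as an independent oracle in the tests.  The foot is treated
as massless for the moment balance; a foot-mass extension was considered
and left out because it adds parameters the rest of the pipeline cannot
estimate.

## Boundary construction

The forward-fall boundary is the trajectory that stops the CM exactly
over the toe under maximal admissible plantarflexion; the backward-fall
boundary mirrors it through the heel under maximal dorsiflexion; the
zero-torque curve coasts into the upright equilibrium.  All three
terminal states are saddle points of the time flow (the extremal torque
exactly holds the terminal state), so backward time-integration stalls
there.  Instead the curves are integrated with θ as the independent
variable, propagating w = ω² through dw/dθ = 2·ω̇_extremal(θ, w) by
fixed-step RK4 (default 800 steps per branch).  Each boundary has two
branches through its terminal (posterior, ω < 0, and anterior, ω > 0);
they are merged into a single curve v(x) in normalized coordinates
(x in foot lengths posterior of the toe, v = u̇/height).

When a physiological torque limit is weaker than the CoP limit, the
holdable rest state is strictly inside the foot; the terminal is then the
root of the extremal static acceleration, found by bracketed bisection.
With generous strength the CoP limit binds and the terminal is exactly
the geometric toe/heel (v(0) = 0 and v(1) = 0).

The zero-torque curve starts from an ε-perturbation of the upright
equilibrium (default ε = 1e-6 rad, with the stable-manifold expansion
w ≈ g ε²/l).  The θ grid is anchored at the equilibrium, not at the
ε-start, so the sampled curve is insensitive to ε (halving ε changes it
by < 1e-8).  For the simple model the curve reproduces the closed form
½ l²ω² + g l sin θ = g l to < 1e-6 heights/s.

A branch is truncated where the admissible torque interval becomes empty
(the extremal trajectory itself would slip or tip); the map stores NaN
beyond, and classification refuses to extrapolate.  If the θ→x mapping is
non-monotone (possible for extreme radius profiles) the innermost value
per position is kept and a warning logged.

Classification follows a strict-inequality rule: a state is stable only
if the whole horizontal error bar [x−Δx, x+Δx] lies strictly between the
boundaries; boundary contact is unstable.  The CM position uncertainty Δx
comes from first-order propagation of segment mass-fraction SDs
(Var(u) = Σᵢ σᵢ²(uᵢ − u)², the renormalized-weights derivative), taken at
the worst posture of the trial, or from a fixed override.

## Map similarity

The position-control tolerance W(v) is the horizontal width of the stable
region at velocity v, obtained by inverting both boundary curves
(monotone piecewise-linear, with a running-max envelope; W(0) = 1 foot
length by geometry).  Similarity is 1 − |W_a − W_b| / W_b with the
variable-inertia map as reference b; the validity velocity is the largest
v* with similarity ≥ threshold (default 0.85) for all v ≤ v*.  The
difference-ratio form was chosen over a raw difference so the measure is
scale-free; it is a declared, configurable choice.

## CM estimation from markers

Five sagittal segments (head, trunk, thigh, shank, foot) with uniform
density: each segment CM is the midpoint of its proximal/distal markers
(bilateral markers averaged first), the body CM is the mass-fraction
weighted mean, expressed ankle-relative.  Arms are excluded and the
fractions renormalized; the shipped default table (head .090 ± .009,
trunk .552 ± .028, thigh .222 ± .016, shank .103 ± .007, foot .033 ±
.003) follows standard gait-analysis anthropometry, and the SDs are sized
so the propagated CM position error is of order ±1.5 cm, the figure
typically quoted for segmental models.  Everything is configurable
through the subject JSON; nothing is hard-coded downstream.

Frames with missing markers are excluded and reported; more than 20%
gaps is an error.  Angular velocity comes from central differences,
optionally after a zero-phase 2nd-order Butterworth low-pass on θ
(default cutoff 6 Hz at 120 Hz sampling — a conventional kinematics
choice; the filter affects ω only, never l).

## Synthetic data

The generator emulates a small healthy-adult cohort: heights 1.62–1.88 m,
masses 55–90 kg, foot length 0.152·height, heel 25% of the foot behind
the ankle, ankle height 0.039·height, μ = 0.8 (shoe on lab floor), and
mass-scaled torque limits (defaults 1.8 / 0.5 N·m/kg plantar/dorsi; the
tests and the acceptance script use an explicit generous-strength
condition, 2.2 / 0.8 N·m/kg, so the boundaries are geometry-limited — the
regime stability maps describe).  Radius profiles are built directly in
the fitted cubic family, anchored at 0.55·height upright and shrinking
with posterior lean by a configurable relative amplitude (default 0.2,
about two-thirds of the sitting-to-standing radius change in adults);
profiles that would cross l ≤ 0 are rejected and retried with damped
amplitude.

Marker trials place a 15-marker, 5-segment kinematic chain so that its
segmental CM equals the forward-simulated pendulum CM *exactly* (foot,
shank and thigh follow a smooth crouch schedule; trunk and head absorb
the residual along the trunk axis).  This makes the noiseless
generator→estimator round trip exact to machine precision, which is what
the recovery tests exploit.  Gaussian marker noise is added per marker
and coordinate.  The natural-trial control policy tracks a velocity
target one safety margin (default 0.08 heights/s) above the zero-torque
velocity and fades to rest just past upright — emulating the observation
that natural sit-to-stands carry extra kinetic energy as insurance
against the backward fall, at the cost of efficiency.

What the generator does *not* emulate: soft-tissue artifact, marker
occlusion patterns, asymmetric (non-sagittal) movement, trunk-strategy
variability, and any deviation of the true radius from the cubic family.
Passing tests therefore show internal consistency of the method and its
software, not validity of the cubic radius model for real subjects.

## The exhaustive-control oracle

Ground-truth labels for seat-off states come from a breadth-first search
over piecewise-constant controls: at each of 8 segments of 0.2 s the
controller picks one of 5 fractions of the current admissible torque
interval (the fraction is held while the interval is re-evaluated every
1/60 s sub-step, so every candidate is admissible by construction).
Branches are deduplicated per start state on a 240×240 (θ, ω) bin grid,
which makes the search a reachable-set sweep rather than a 5⁸
enumeration.  A state is *success* when some branch brings the CM over
the BOS at |v| ≤ 0.02 heights/s with the static hold admissible;
*failure* when every branch dies (empty torque interval or leaving the θ
domain); *indeterminate* when live branches outlast the 1.6 s horizon —
those are excluded from scored cohorts.  On 15×15 state grids the oracle
agrees with boundary-interpolation membership in ≈ 99% of cells, with
disagreements confined to cells the boundary passes through.

## Problem sizes and numerical defaults

Map grid x ∈ [−0.2, 3.0] with 400 samples (seat-off distances beyond
2.4 foot lengths occur in demanding stand-ups); 800 θ-steps per boundary
branch; RK4 everywhere, fixed step (1/120 s in trial simulation, 1e-4 s
in convergence tests).  Cohorts of 150 states and 20-seed noise studies
keep the full acceptance run under a minute on one core.  Stable-region
areas are compared over a fixed position window (default [−0.2, 1.9]
foot lengths) because boundary coverage ends where the extremal
trajectory itself becomes infeasible, and that endpoint moves with the
constraint parameters.

## Known limitations

* One degree of freedom: stepping, grasping, hip-strategy recovery and
  frontal-plane balance are out of scope by construction.
* The radius cubic is fitted on the observed θ range only; maps are not
  extrapolated beyond it, so strongly varying profiles yield maps that
  end before x = 3.
* The foot is massless in the CoP balance; heavy footwear would shift
  the no-tip interval slightly.
* Sensitivity/specificity are pooled over trials; per-subject
  breakdowns are available from the classification table but no
  cross-subject inference is attempted.
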