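# Methods

`toadhop` analyses forelimb landing preparation in hopping anurans from
marker-based kinematics.  This note records the models, conventions,
numerical choices, and limitations behind the implementation.

## Conventions

Analysis is planar.  The direction of travel is the dominant horizontal
displacement of the snout marker over the recording; all velocities are
projected onto the sagittal (travel, vertical) plane, with `z = 0` at the
landing surface and `z` positive up.  Angles are degrees from horizontal,
positive above:

* **α** (forelimb angle): angle of the mid-humerus → wrist segment.  A
  forelimb held parallel to the ground reads 0°; a wrist straight below
  the humerus reads −90°.
* **γ** (velocity-vector angle): angle of the snout's instantaneous
  velocity, positive ascending, negative descending.  γ at touchdown is
  the impact angle, γ_TD.
* **δ = γ − α** at every frame, exactly; δ_TD is δ at first manus
  (wrist-marker) touch.

With this signed convention, an arm held on average 4.1° steeper than the
impact velocity corresponds to a mean δ_TD of −4.1°.

## Smoothing and differentiation

Each marker coordinate is fitted per axis with a degree-5 smoothing spline
(FITPACK); velocities and accelerations are the spline's analytic
derivatives, never finite differences of smoothed values.  With zero
penalty the interpolating quintic spline reproduces sampled polynomials of
degree ≤ 5 and their derivatives exactly, which anchors the test suite.

The smoothing parameter is the FITPACK residual target `s`.  The default
`"auto"` rule sets `s = n·σ̂²` per axis, with `σ̂` the second-difference
noise estimator `σ̂² = Σ(Δ²x)²/(6(n−2))` — the classic residual-matching
choice, requiring no effective-degrees-of-freedom trace (which FITPACK
does not expose for quintic fits).  The chosen `s` is recorded per marker
and axis in the analysis output; an explicit numeric override is
available in the configuration.

Smoothing-spline derivatives ring at the first and last frames of a
recording.  Rather than padding the data (reflection padding either
preserves or suppresses the noisy boundary slope, both of which bias the
derivative), the event detectors are written to be insensitive to
boundary frames (below).

## Event detection

* **Hop initiation T₀**: first frame with 3-D snout speed above 5 cm/s.
  The crossing is located by walking back from the frame of peak speed to
  the last preceding sub-threshold frame, which equals the plain
  first-crossing rule on clean data but ignores spurious boundary-frame
  crossings.  Whether the original rule used 3-D or sagittal speed is not
  determinable; 3-D speed is used.
* **Inclusion filter**: a hop enters the analysis only if the vertical
  velocity at T₀ is strictly upward (downward launches off a raised
  platform are excluded; `v_z(T₀) = 0` exactly is excluded by the strict
  inequality).
* **Lift-off**: first frame after T₀ from which the snout's vertical
  acceleration stays within 15% of −g over the following 10 ms, judged on
  the window median so isolated noisy frames do not move the onset.
* **Touchdown**: first frame after the aerial apex at which the wrist
  marker falls below 3 mm above the landing surface with downward wrist
  velocity.  The wrist is the closest digitized point to the manus, so
  wrist contact proxies first manus touch.  On clean data the 3 mm
  tolerance can fire one frame earlier than a 0 mm tolerance (descent is
  ~2.4 mm/frame at 500 fps); both are within the 2-frame detector
  tolerance used throughout.

On noise-free simulations all three detectors agree with ground truth to
within 2 frames (4 ms) at 500 fps.

## Alignment band and timing

δ_TD values of included hops are pooled (across the whole dataset by
default; per treatment or per animal by configuration) into an alignment
band centred on their mean.  Two band constructions are implemented:

* `fixed_halfwidth` (default): mean ± 15°.
* `ci_of_mean`: the 95% t-interval of the mean, mean ± t₀.₉₇₅,ₙ₋₁·SD/√n.

The fixed half-width is the default because the CI of the mean shrinks as
1/√n: with hundreds of hops the band collapses to ~1°, so "alignment"
would become stricter the more data one collects and no physiological
tracking noise could remain inside it continually.  The ±15° criterion is
scale-free in the number of hops.

**T_a** is the earliest frame in [T₀, touchdown] at which δ lies in the
band, with the entry required to persist for 20 ms: just after T₀ the
snout barely exceeds the speed threshold, so the velocity direction — and
hence δ — is briefly noise-dominated and can brush the band for a frame
or two without the arm being anywhere near aligned.  A converged arm
stays in the band, so the persistence rule leaves genuine entries
unchanged (verified against ground truth on clean simulations).
**Continual alignment** requires every frame from T_a through touchdown
inside the band, with a configurable dropout tolerance in frames
(default 0).  Onsets are reported relative to hop initiation
(O_T0 = T_a − T₀) and lift-off (O_LO = T_a − lift-off); the alignment
duration is D_a = touchdown − T_a.  The **excursion** is the endpoint
difference |γ(T_a) − γ(touchdown)|; the total variation of γ over that
window would be an alternative reading, not used here.

## Synthetic hops

The generator emulates the study design the analysis assumes: 6 animals,
three platform heights (0, 5, 9 cm), 6–12 hops per animal per condition,
500 frames/s, with ground truth recorded for every hop.  Each hop has
three phases:

1. **Initiation** (0.20 s): the snout accelerates from rest along the
   takeoff direction with speed `v(t) = v₀(t/T_i)⁶`.  The high exponent
   keeps the pre-lift-off displacement short (a few cm) so the snout
   stays above the platform while still crossing the 5 cm/s threshold,
   with upward velocity, well before lift-off.
2. **Aerial**: point-mass projectile from the lift-off height
   (platform + 5.5 cm) with g = 9.81 m/s²; per-hop takeoff speed uniform
   in 1.2–2.2 m/s and angle uniform in 30–55°.
3. **End**: the recording stops a few frames after the wrist first
   reaches the landing surface on descent.

The forelimb policy is a behavioural model, not a measured mechanism: the
arm tracks the target `γ(t) − δ*` with an initial error of 75° at hop
onset that decays exponentially (time constant 40 ms) plus AR(1) jitter
(stationary SD 3°, correlation time 120 ms).  The tracking error is
modelled as decaying rather than the arm lagging a moving target because
any first-order lag long enough to matter produces tens of degrees of
error near the hop apex, where γ sweeps at hundreds of degrees per
second — incompatible with the degree-scale touchdown offsets the design
emulates.  The jitter correlation time reflects that an inertial limb
cannot jitter at the 2 ms frame scale; frame-scale noise enters instead
as 0.5 mm Gaussian marker noise.  δ* has population mean −4.1° and
per-animal intercepts with SD 3°.

What the generator does **not** emulate: the early rise of |δ| during
trunk elevation (δ converges monotonically here), body deformation (the
snout is a point mass; the arm geometry is rigid), ground contact during
the crouch (the wrist may pass below the surface plane before lift-off;
detectors only consider the post-apex descent), hind limbs, and any
kinetics after impact.  Passing tests therefore certify the measurement
chain and statistics under these conditions, not the behaviour of real
animals.

## Landing torque model

At impact the body is a point mass (COM) with the forelimb as a rigid
segment contacting the ground at one point, and the ground reaction force
is parallel to the impact velocity and opposing it:
`F̂ = −(cos γ, sin γ)`.  The net torque about the COM is the 2-D cross
product `τ = (com − contact) × F`, positive when the body pitches forward
over the contact in the direction of travel; the moment arm is
`|τ|/|F|`.  The model is a static snapshot — no impulse dynamics, angular
velocity, or muscle action — because the question it serves is how the
limb is oriented *before* impact.  When the COM lies on the limb line,
α = γ zeroes the torque, and |τ| grows monotonically with |α − γ| within
±30°: the geometric core of the alignment hypothesis.

`torque_minimizing_arm_angle` minimizes |τ| over α for a
shoulder-anchored limb by a 0.1° grid scan plus bounded refinement of
every local minimum (tolerance 10⁻⁴ °); when several angles achieve the
minimum (the torque typically has two zeros) the one nearest γ is
returned.

## Statistics

All mixed models are Gaussian random-intercept LMMs fitted by maximum
likelihood — not REML — because every reported inference is a
fixed-effect likelihood-ratio test and only ML likelihoods are comparable
across fixed-effect designs.  For a fixed variance ratio
λ = σ_b²/σ_e², β and σ_e² are profiled in closed form (block Sherman–
Morrison); the fit is a 1-D bounded search over log λ with the λ = 0
boundary always evaluated.  The fitted maximum agrees with a dense
multivariate-normal likelihood evaluation to 10⁻⁶ and with statsmodels'
`MixedLM` (ML) in the tests.

LRTs use χ² with df equal to the difference in fixed-effect counts:
treatment (3 levels) gives df = 2; a single covariate (e.g. platform
height) gives df = 1.  The statistic is clamped at zero; identical
designs give χ² = 0, p = 1.  No multiple-testing correction is applied.
Cohort summaries are means of individual means: each animal contributes
one mean per cell and animals are averaged, so animals with more hops do
not dominate (guarding against pseudo-replication).

Per-animal regressions are OLS of α_TD on γ_TD with a two-sided slope
test, requiring ≥ 3 included hops and a non-constant predictor.

## Problem sizes

The validation suite uses cohorts of 6 animals × 3 treatments × 8 hops
(~144 hops) across 20 seeds for the noisy-recovery and headline-pattern
checks, a 54-hop noise-free cohort for the event-detection oracle, 500
replicates for the LRT type-I calibration, and 50–100 random geometries
for the torque oracles.  These sizes give sampling error comfortably
below every tolerance tested while keeping a full run in tens of seconds.

## Known limitations

* The α/γ sign convention differs from reports that treat steeper arms
  as larger positive angles; magnitudes convert directly, signs flip for
  descending quantities.
* The band's ±15° half-width and the 20 ms entry-persistence window are
  analysis constants, both exposed in configuration; results near the
  band edge (animals whose δ* sits far from the pooled mean) are
  sensitive to the half-width.
* γ is undefined (NaN, never interpolated) wherever planar speed falls
  below 10⁻⁶ m/s, and is unreliable just above the initiation threshold;
  the persistence rules absorb this, but per-frame δ values within
  ~20 ms of T₀ should not be over-interpreted.
* The LMM supports a single random intercept (animal); crossed or nested
  random structures and Satterthwaite/Kenward–Roger df corrections are
  out of scope.
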