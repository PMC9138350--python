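# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the design decisions behind `myoexo`, including what the
package's tests do and do not demonstrate about real recordings.

## Model and assumptions

### EMG to activation

Raw surface EMG is processed per channel: zero-phase 4th-order Butterworth
band-pass (20–450 Hz), full-wave rectification, zero-phase 2nd-order
Butterworth low-pass at 8 Hz, division by the channel's
maximum-voluntary-contraction (MVC) level, and clipping to [0, 1].  Both
filter stages are applied forward-backward so the filters add no phase
delay of their own; the physiological lag is modelled explicitly by the
electromechanical delay `d` (integer samples, default 40 = 40 ms at 1 kHz).

Neural activation follows the standard damped second-order recursion
u(t) = α e(t−d) − β₁ u(t−1) − β₂ u(t−2).  The recursion must be stable
(roots of z² + β₁z + β₂ inside the unit circle) and physiological
parameter sets impose unit DC gain α = 1 + β₁ + β₂; the
`ActivationParams.from_poles(c1, c2)` constructor builds such sets from the
pole factors (β₁ = c₁ + c₂, β₂ = c₁c₂, poles at −c₁, −c₂).  The raw
constructor accepts any stable coefficients, so non-unit-gain sets from the
literature remain representable.  Muscle activation is
a = (e^{Au} − 1)/(e^A − 1) with shape factor −3 < A < 0 (strictly; values
at the boundary are rejected).

No numeric values of α, β₁, β₂, d are fixed by the hardware study this
model family comes from; the defaults here (double pole at 0.35, d = 40)
are fixture choices.

### Muscle–tendon units

Lengths are normalised: fiber length l = L/L\*, tendon strain
ε = (l_t − l_slack)/l_slack.  The strain is measured relative to the slack
length (a literal reading "ε = l_t/l_slack" would give unit strain at slack
length and contradict the requirement that a just-taut tendon transmits no
force).

* active force–length: f_l(l) = exp(−(l−1)²/γ), γ = 0.45;
* passive: f_pe(l) = (e^{k(l−1)/ε_pe} − 1)/(e^k − 1), k = 5, ε_pe = 0.6
  (slightly negative below l = 1, as the raw formula gives; magnitudes
  there are below 0.007);
* tendon: zero below zero strain, exponential toe
  f_toe (e^{k_toe ε/ε_toe} − 1)/(e^{k_toe} − 1) up to ε_toe, linear with
  slope k_lin above.  Defaults f_toe = 0.33, k_toe = 3, ε_toe = 0.02.
  k_lin defaults to the C1 match of the toe-region end slope (≈ 52.1 for
  the default toe constants), which removes a derivative kink at ε_toe and
  puts the strain at maximum isometric force near the textbook 3.3%.  A C0
  anchor with a steeper slope is available by passing k_lin explicitly.
* force–velocity, inverted for the fiber ODE:
  v = (0.25 + 0.75a) V_max (f_ce − a f_l(l))/b, V_max = 10 L\*/s, b = 0.25.
  The (0.25 + 0.75a) factor uses the activation; b is a shape constant.

Series equilibrium: given the path length l_mt and fiber length, the tendon
length is l_t = l_mt − L\* l cos α_pen, the tendon force f_se follows from
its strain, and the contractile demand is f_ce = f_se/cos α_pen − f_pe(l),
clamped at zero because fibers cannot push (the clamp is a flag, not an
error).  The force transmitted to the joint is F_mt = f_se F_max.

### Joint coupling and geometry

The muscle-torque sum needs moment arms for dimensional consistency; each
muscle gets a constant signed arm r (extensors +0.04 m, flexors −0.035 m by
default) and the affine path closure l_mt(θ) = l_mt0 − r(θ − θ_r), which is
the unique geometry consistent with τ = rF and dl_mt/dθ = −r.  The default
reference path length is l_mt0 = L\* cos α_pen + l_slack: at the rest angle
a passive muscle sits at its optimal fiber length with the tendon just
taut, so the fully passive rest pose is an exact global fixed point of the
coupled dynamics.  Angle convention: θ = 0 full extension, increasing with
flexion, θ_r = π/2; radians everywhere internally, degrees only at I/O.

The default muscle set is the identified-subject table bundled as
`TABLE_SUBJECT_CM` (eight muscle–tendon units; the vastus lateralis /
medialis / intermedius share the VM channel, the semimembranosus and
semitendinosus the ST channel, the two biceps femoris heads the BF
channel).

### Rigid-body joint and identification

J θ̈ + B θ̇ + K(θ−θ_r) + τ_g sin(θ−θ_r) = τ_e + τ_h with τ_g = m g r_cm.
Defaults J = 0.07 kg m², B = 1.5 N m s/rad, K = 1.27 N m/rad, m = 5.5 kg,
r_cm = 0.16 m.  K is identified from static holds (120° to 0° in 15°
steps) as the closed-form no-intercept least-squares slope of
y = τ_e − τ_g sin(θ−θ_r) on (θ−θ_r); J and B from slow driven movement by
linear least squares on y = Jθ̈ + Bθ̇, with θ̇ and θ̈ obtained by
analytically differentiating a truncated Fourier fit of the encoder angle
(default 8 harmonics of the commanded base period).  The gravity torque
scale τ_g is constant in time.  Both problems are linear in the
parameters, so the closed forms are exact; a Levenberg–Marquardt solver
over the same residuals is retained as an option and reaches the same
optimum.

### Calibration loss and adjoint

The loss is the running cost ℓ(ω) = ∫ (ż − θ̇_meas)² dt over the fit
window (flat prior on the torque — the estimation is maximum-a-posteriori
with the prior term set to zero, with a hook for future priors).  With
state x = (l₁..l_n, θ, θ̇) the continuous adjoint is

    dλ/dt = −(∂f/∂x)ᵀ λ − (∂g/∂x)ᵀ,   λ(T) = 0,
    dℓ/dω = ∫₀ᵀ λᵀ ∂f/∂ω dt + λ(0)ᵀ ∂x₀/∂ω,

where the running-cost source ∂g/∂x = 2(ż − θ̇_meas) acts on the θ̇
component throughout the window (the loss is an integral, not a terminal
cost).  The adjoint spans the full state — the fiber lengths couple into
the torque, so λ carries their sensitivities too.  The second term exists
because the initial fiber lengths are the isometric equilibrium of the
*candidate* parameters (below); it is computed by implicit differentiation
of the equilibrium condition and verified against finite differences in the
tests.  ∂f/∂x and ∂f/∂ω are hand-derived analytic expressions; the test
suite cross-checks them by complex-step differentiation of the rhs (the
rhs is written complex-safe for exactly this purpose).

One gradient costs exactly one forward and one backward ODE solve,
regardless of the number of parameters — the accounting that makes the
analytic route competitive with gradient-free methods while two-point
finite differencing costs n+1 loss evaluations per gradient.

## Numerical choices

* **Integrator.** Adaptive Runge–Kutta–Fehlberg 4(5), advancing with the
  5th-order solution (global order ~5, verified by a fixed-step convergence
  test), error norm mixing atol and rtol, step factors clipped to
  [0.2, 5].  Dense output is cubic Hermite on accepted steps; the backward
  pass interpolates the forward cache instead of re-integrating the state
  in reverse (the muscle equilibrium is unstable backward in time).
  Defaults rtol 1e−7/atol 1e−9 for simulation; 1e−6/1e−8 for fitting;
  1e−12/1e−14 in gradient-verification runs.  Step-size underflow raises
  an error naming the failure time.
* **Loss quadrature.** Inside fit problems the loss is carried as an extra
  quadrature state q′ = (ż − θ̇_meas)², so its value is error-controlled by
  the integrator; computing it afterwards from the dense output leaves
  interpolation noise (~1e−8) that caps finite-difference reproducibility
  near 1%.  The measured velocity enters as a C2 cubic spline of the
  (uniformly sampled) reference.  The public `trajectory_loss` helper uses
  plain trapezoid quadrature on the measurement grid.
* **Initial state.** Fiber lengths start at the isometric equilibrium for
  the activation at t₀ (the passive equilibrium is the a₀ = 0 special
  case).  A passive initialisation under tonic activation would start the
  state exactly on the tendon-slack corner of the piecewise model and
  create a startup transient; the activation-consistent equilibrium avoids
  both.  The equilibrium bracket widens automatically for extreme candidate
  parameters.
* **Optimizer.** Adam (β = 0.9/0.999, lr 1e−2) on log ω keeps all
  parameters positive; updates are boxed within a factor 30 of the nominal
  parameters because flat (unidentified) coordinates otherwise drift
  without limit under Adam's sign-normalised steps.  A divergence guard
  aborts if the loss grows 10× over 20 iterations.  Exactly 2 loss-grade
  evaluations are logged per iteration.
* **Compiled kernels.** The forward and backward solves have
  numba-compiled twins of the numpy reference implementations (~100×
  faster); activations are frozen onto a 1 kHz linear-interpolation grid
  for both paths so they solve the identical problem, and tests assert
  their agreement.  Without the kernels the shared-start benchmark would
  take on the order of an hour instead of minutes.
* **Simplex baselines.** Nelder–Mead and adaptive Nelder–Mead are scipy's
  implementations behind an evaluation-counting proxy; infeasible simplex
  proposals (negative lengths or forces) receive a large penalty value.
  One iteration = one simplex update.

## Synthetic data: what it emulates and what it does not

The generator produces per-channel activation bursts (squared half-sines,
raised-cosine pulses, or ramps) in the slow movement band 0.01–0.5 Hz, with
a 5% MVC tonic co-contraction floor.  The tone represents resting muscle
activity and antagonist co-activation; it also keeps every tendon taut
through the cycle, so the nominal trajectories stay inside the smooth
regime of the piecewise model — consistent with posing a differentiable
simulation problem.  Surrogate EMG is a 20–450 Hz Gaussian carrier,
normalised to unit short-time rectified mean, amplitude-modulated by the
envelope whose image under the activation dynamics is the requested
activation, plus a white noise floor (default 20 dB SNR).  Ground-truth
trajectories are exact forward solutions of the true parameters; encoder
noise (default 0.5°) is optional and seeded.  The default movement
amplitude is calibrated by a few coarse forward solves so the knee sweeps
the 45° flexion–extension task; the optimizer-benchmark fixture instead
spans ~90° (the recording protocol covers 0–100° of flexion) over two
cycles at different burst amplitudes with flexor bursts boosted 1.8×,
because a wide, varied excursion is what makes length parameters
identifiable at all from a single session.

What passing tests do **not** show about real data: the surrogate EMG has
none of the nonstationarity, motion artifacts, crosstalk or electrode-lift
events of real recordings; activations are exactly the inverse image of
the designed envelopes, whereas real activation dynamics are only
approximately second-order; and the noise-free recovery experiments start
from a model that is exactly correct, so they measure optimizer and
gradient quality, not model adequacy.

## Identifiability and the spread experiment

From 10 shared starts (lengths jittered uniformly within ±5 cm, forces
unperturbed — the stated bounds are lengths; an optional mode adds ±20%
multiplicative noise to F_max), the adjoint-Adam route and Nelder–Mead are
run for 200 iterations each and the spread (max − min across starts) of
the channel-group means of L\* and l_slack is tracked for the VM and ST
groups (the model presents VM/ST as groups, and group-average muscle
quantities are the natural observable).

Muscles sharing an EMG channel contribute only their summed torque, so the
individual parameter split within a group is fundamentally under-determined
from one session; even 2000-iteration runs do not move the hamstring slack
lengths toward the generating values while the loss sits at its floor.  In
practice the VM L\*/l_slack and ST L\* group spreads contract well below
their starting values and end below Nelder–Mead's, while the ST l_slack
spread is flat-to-slightly-growing and seed-dependent — an honest
reflection of a null direction through the two hamstring slack lengths.
The corresponding acceptance test asserts contraction for all four tracked
quantities and is expected to fail for ST l_slack.

## Experiment sizes

The standard verification experiments use these problem sizes (all chosen
as the package's own defaults):

* gradient verification: 10 random parameter draws each on a 1-muscle
  (±20%, 2 s window) and the 8-muscle 45° problem (±10%, 4 s window), at
  rtol 1e−12, against Richardson-extrapolated central differences with
  relative base step 5e−4 (the acceptance script reports the same check
  with 5 draws per problem);
* shared-start benchmark: 10 perturbed starts, 200 optimizer iterations,
  two-cycle 8 s session spanning ~90°;
* identification: the 9-hold static protocol and a 20 s, 100 Hz dynamic
  record mixing 0.1/0.25/0.4 Hz components.

## Known limitations

* Constant moment arms and affine path lengths; no wrapping surfaces or
  angle-dependent arms.
* Constant pennation; no fatigue or history dependence.
* Explicit integration only: very stiff tendon settings (large k_lin, short
  slack lengths) force millisecond steps; stiff implicit solvers are out of
  scope.
* The one-sided derivative is used at the tendon-slack and CE-clamp kinks;
  gradient checks are therefore performed on trajectories that stay in the
  smooth regime.
* The PID controller is a discrete 100 Hz implementation with
  derivative-on-measurement filtering (first-order, 10 Hz) and conditional
  anti-windup; with zero gains the closed loop reproduces the open-loop
  plant to integration tolerance (not bitwise — the co-simulation
  integrates in controller-tick segments).
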