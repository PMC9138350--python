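# myoexo

EMG-driven musculoskeletal simulation for a single-joint (knee) exoskeleton,
with analytic adjoint gradients for calibrating the per-muscle parameters of
a Hill-type model against measured joint trajectories.

`myoexo` is aimed at people building EMG-based assist-as-needed controllers
or studying subject-specific muscle calibration: it turns multichannel
surface EMG into muscle activations, couples eight knee muscle–tendon units
to a rigid-body joint model, and fits each muscle's optimal fiber length
L\*, maximum isometric force F_max and tendon slack length l_slack so that
the simulated joint velocity matches a recording — using exact gradients at
a cost of two ODE solves per iteration, independent of the number of
parameters.

## The model

**Activation.** Band-passed (20–450 Hz), rectified, low-passed (8 Hz) and
MVC-normalised EMG e(t) drives a damped second-order recursion
u(t) = α e(t−d) − β₁ u(t−1) − β₂ u(t−2) (electromechanical delay d, unit DC
gain), then the shaping nonlinearity a = (e^{Au} − 1)/(e^A − 1), −3 < A < 0.

**Muscle–tendon units.** Each muscle is a contractile element with Gaussian
active force–length f_l(l) = exp(−(l−1)²/γ) and exponential passive curve
f_pe, in series with a tendon whose force–strain curve has an exponential
toe region and a linear region above it.  Series equilibrium
F_se = F_m cos α_pen closes the model; the fiber velocity follows from the
inverted force–velocity relation
v = (0.25 + 0.75a) V_max (f_ce − a f_l(l)) / b.

**Joint.** The exoskeleton-plus-shank is a damped pendulum-like joint
J θ̈ + B θ̇ + K(θ−θ_r) + τ_g sin(θ−θ_r) = τ_e + τ_h with gravity torque
τ_g = m g r_cm, assist torque τ_e (PID-controlled), and muscle torque
τ_h = Σ_j r_j F_mt^{(j)}.  J, B and K are identified from static and
dynamic protocols by linear least squares with Fourier-series smoothing of
the encoder signal.

**Calibration.** With ω = (L\*, F_max, l_slack) per muscle, the loss
ℓ(ω) = ∫ (ż(t; ω) − θ̇_meas(t))² dt is minimised by Adam on log ω.  The
gradient comes from the continuous adjoint: λ(t) solves
dλ/dt = −(∂f/∂x)ᵀλ − (∂g/∂x)ᵀ backward from λ(T) = 0, and
dℓ/dω = ∫ λᵀ ∂f/∂ω dt + λ(0)ᵀ ∂x₀/∂ω.  Integration uses an adaptive
Runge–Kutta–Fehlberg 4(5) pair with dense output; the forward and backward
passes run through numba-compiled kernels, with a pure-numpy reference path
that the test suite checks against them.

Everything runs offline: a synthetic-data module generates activation
profiles, band-limited surrogate EMG, and ground-truth trajectories, so all
experiments are reproducible from a seed without any recordings.

## Worked example

```python
import numpy as np
from myoexo import (ExoParams, FitProblem, fit_parameters,
                    identify_inertia_damping, identify_stiffness,
                    make_dynamic_record, make_experiment, make_static_record,
                    perturb_omega)

exo = ExoParams()
K = identify_stiffness(make_static_record(exo), exo.m, exo.r_cm, exo.theta_r)
J, B = identify_inertia_damping(make_dynamic_record(exo), K, exo.m, exo.r_cm,
                                exo.theta_r, n_harmonics=10)

fix = make_experiment(seed=1, with_emg=False)     # synthetic 45-deg session
problem = FitProblem.from_system(fix.system, fix.activations, (0.0, 5.0),
                                 rtol=1e-6, atol=1e-8)
start = perturb_omega(problem.system.omega_vector(), 1,
                      np.random.default_rng(1), noise_m=0.03)[0]
result = fit_parameters(problem, omega0=start, max_iter=120, lr=1e-2)
```

prints (via the surrounding report statements):

```
identified K = 1.2700 N m/rad, J = 0.0700 kg m^2, B = 1.5000 N m s/rad
joint excursion: 46.7 deg over 5 s
loss: 0.0081 -> 7.47e-06 in 120 iterations (2 loss evaluations per iteration)
angular-velocity tracking error: 0.35% RMS of signal
vastus lateralis: L* = 11.9 cm, F_max = 2316 N, l_slack = 10.7 cm  (truth: 9.6 cm, 2260 N, 12.9 cm)
```

The identification is exact on noise-free protocols.  The calibration
reduces the velocity-matching loss by three orders of magnitude and tracks
the reference trajectory to a fraction of a percent; the fitted per-muscle
lengths land on the data-consistent manifold rather than exactly on the
generating values — with several muscles sharing one EMG channel, only
group-level combinations are fully identified (see `docs/methods.md`).

## Command line

The library is also a shell tool with six subcommands, each driven by a
YAML config and a seed:

```
myoexo generate   --config cfg.yaml --out fixture/   --seed 1   # synthetic session (EMG + trajectories)
myoexo preprocess --config cfg.yaml --emg emg.csv --out act.csv # EMG -> activation
myoexo identify   --config cfg.yaml --static s.csv --dynamic d.csv --out ident.json
myoexo fit        --config cfg.yaml --out fit.json  --seed 1    # adjoint calibration
myoexo simulate   --config cfg.yaml --out traj.csv  --seed 1    # PID-assisted closed loop
myoexo benchmark  --config cfg.yaml --out bench.json --seed 1   # optimizer comparison
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.

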