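"""Fully synthetic experiments: activations, EMG emulation, trajectories.

Everything downstream (identification, calibration, benchmarking) is
testable offline from fixtures built here:

* smooth per-channel activation profiles for reciprocal knee
  flexion-extension in the slow movement-frequency range (0.01-0.5 Hz);
* band-limited surrogate EMG: a 20-450 Hz Gaussian carrier amplitude-
  modulated by the envelope whose image under the activation dynamics is the
  requested activation, plus an additive noise floor (so the preprocessing
  chain round-trips);
* ground-truth trajectories: the exact forward solution of the coupled
  muscle-joint ODE under the true parameters, optionally with Gaussian
  encoder noise;
* static and dynamic identification protocols replicating the exoskeleton
  procedures (holds from 120 deg to 0 in 15 deg steps; slow sinusoidal
  sweeps).

The default ground-truth muscle set is the identified-subject parameter
table bundled with the muscle module, so parameter-recovery experiments are
anchored to printed values.  The default movement amplitude is calibrated so
the knee sweeps approximately the 45 degree flexion-extension task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .dynamics import ExoParams, MuscleJointSystem, Trajectory, simulate
from .identification import DynamicRecord, StaticRecord
from .muscle import MuscleParams, default_knee_muscles
from .signals import ActivationParams, SignalTrace, muscle_activation

__all__ = [
    "ExperimentFixture",
    "make_activation_profiles",
    "emulate_emg",
    "make_experiment",
    "make_benchmark_experiment",
    "make_static_record",
    "make_dynamic_record",
    "DEFAULT_CHANNEL_ORDER",
]

DEFAULT_CHANNEL_ORDER = ("RF", "VM", "ST", "BF")
_EXTENSOR_CHANNELS = ("RF", "VM")

#: documented fixture choices (not measured values)
DEFAULT_ENCODER_NOISE_DEG = 0.5
DEFAULT_EMG_SNR_DB = 20.0
DEFAULT_EMG_FS = 1000.0


#: tonic co-contraction floor (fraction of MVC) added to every profile;
#: antagonist co-activation of this size is typical in knee
#: flexion-extension and keeps the tendons taut between bursts
DEFAULT_TONE = 0.05


def make_activation_profiles(pattern="reciprocal_sine", t_span=(0.0, 5.0),
                             rate_hz=0.2, amplitude=0.12, seed=0,
                             channels=DEFAULT_CHANNEL_ORDER,
                             baseline=DEFAULT_TONE):
    """Smooth per-channel activation profiles in [0, 1].

    Patterns: ``reciprocal_sine`` (squared half-sine bursts, extensors and
    flexors in antiphase), ``pulse_train`` (raised-cosine bursts), ``ramp``
    (triangular ramp on extensors only).  Every profile carries a small
    tonic ``baseline`` emulating resting muscle tone.  Returns
    ``{channel: callable}``.
    """
    if not (0.01 <= rate_hz <= 0.5):
        raise ValueError("movement rate outside the 0.01-0.5 Hz protocol")
    w = 2 * np.pi * rate_hz
    t0 = t_span[0]

    def half_sine_sq(sign):
        def f(t):
            s = sign * np.sin(w * (np.asarray(t, dtype=float) - t0))
            return np.clip(baseline + amplitude * np.clip(s, 0.0, None) ** 2,
                           0.0, 1.0)
        return f

    def pulse(sign):
        def f(t):
            ph = (np.asarray(t, dtype=float) - t0) * rate_hz % 1.0
            c = 0.25 if sign > 0 else 0.75
            win = 0.5 * (1 + np.cos(np.clip((ph - c) / 0.18, -1, 1) * np.pi))
            return np.clip(baseline + amplitude * win, 0.0, 1.0)
        return f

    def ramp(sign):
        def f(t):
            ph = (np.asarray(t, dtype=float) - t0) * rate_hz % 1.0
            tri = 1.0 - np.abs(2 * ph - 1.0)
            burst = amplitude * tri if sign > 0 else np.zeros_like(ph)
            return np.clip(baseline + burst, 0.0, 1.0)
        return f

    makers = {"reciprocal_sine": half_sine_sq, "pulse_train": pulse,
              "ramp": ramp}
    if pattern not in makers:
        raise ValueError(f"unknown pattern {pattern!r}")
    mk = makers[pattern]
    return {ch: mk(+1 if ch in _EXTENSOR_CHANNELS else -1) for ch in channels}


def channel_to_muscle_activation(channel_fns, muscles: list[MuscleParams]):
    """Map per-channel activation callables onto the muscle ordering."""
    def act(t):
        vals = {ch: f(t) for ch, f in channel_fns.items()}
        return np.array([vals[m.channel] for m in muscles])
    return act


def emulate_emg(a: SignalTrace, p: ActivationParams, mvc=1.0,
                snr_db=DEFAULT_EMG_SNR_DB, seed=0) -> SignalTrace:
    """Surrogate raw EMG whose preprocessed envelope reproduces ``a``.

    Inverts the activation chain (activation -> neural drive -> envelope),
    then amplitude-modulates a 20-450 Hz band-limited Gaussian carrier
    normalised to unit rectified mean; an additive white noise floor is set
    by ``snr_db`` (np.inf for a clean carrier).
    """
    rng = np.random.default_rng(seed)
    av = np.clip(a.values, 0.0, 1.0)
    # invert the shaping nonlinearity, then the recursion, then the delay
    u = np.log1p(av * np.expm1(p.A)) / p.A
    e_del = np.empty_like(u)
    e_del[:] = u
    e_del[1:] += p.beta1 * u[:-1]
    e_del[2:] += p.beta2 * u[:-2]
    e_del /= p.alpha
    e = np.empty_like(e_del)
    if p.d > 0:
        e[: e.size - p.d] = e_del[p.d :]
        e[e.size - p.d :] = e_del[-1]
    else:
        e[:] = e_del
    e = np.clip(e, 0.0, 1.0)
    sos = _sig.butter(4, (20.0, 450.0), btype="bandpass", fs=a.fs,
                      output="sos")
    pad = int(a.fs)  # discard causal-filter warmup at both ends
    carrier = _sig.sosfilt(sos, rng.standard_normal(e.size + 2 * pad))
    # normalise to unit short-time rectified mean so the downstream
    # rectify-and-low-pass demodulation recovers the designed envelope
    sos_env = _sig.butter(2, 8.0, btype="lowpass", fs=a.fs, output="sos")
    short_time_mean = _sig.sosfiltfilt(sos_env, np.abs(carrier))
    floor = 0.2 * np.mean(np.abs(carrier))
    carrier = carrier / np.maximum(short_time_mean, floor)
    carrier = carrier[pad : pad + e.size]
    raw = e * carrier * mvc
    if np.isfinite(snr_db):
        p_sig = np.mean(raw**2)
        if p_sig > 0:
            sigma = np.sqrt(p_sig / 10 ** (snr_db / 10))
        else:
            sigma = 0.01 * mvc  # noise floor for silent channels
        raw = raw + sigma * rng.standard_normal(e.size)
    return a.with_values(raw)


@dataclass
class ExperimentFixture:
    """Ground truth plus emulated measurements for one synthetic session."""

    muscles: list[MuscleParams]
    exo: ExoParams
    system: MuscleJointSystem
    activations: object                  # callable t -> per-muscle a(t)
    channel_fns: dict = field(repr=False, default=None)
    activation_params: dict = None       # per-channel ActivationParams
    trajectory: Trajectory = None        # noise-free forward solution
    noisy_trajectory: Trajectory = None
    emg: dict = None                     # per-channel raw SignalTrace
    mvc: dict = None
    seed: int = 0
    amplitude: float = np.nan

    @property
    def theta_range_deg(self) -> float:
        th = self.trajectory.theta
        return float(np.degrees(th.max() - th.min()))


def make_experiment(pattern="reciprocal_sine", t_span=(0.0, 5.0),
                    rate_hz=0.2, amplitude=None, target_range_deg=45.0,
                    seed=0, muscles=None, exo=None, fs_out=100.0,
                    encoder_noise_deg=DEFAULT_ENCODER_NOISE_DEG,
                    snr_db=DEFAULT_EMG_SNR_DB, emg_fs=DEFAULT_EMG_FS,
                    with_emg=True, rtol=1e-7, atol=1e-9) -> ExperimentFixture:
    """Compose activations -> forward dynamics -> measurements.

    If ``amplitude`` is None the activation amplitude is calibrated with a
    few coarse forward solves so the joint sweeps ``target_range_deg``
    (default: the 45 degree flexion-extension task).
    """
    muscles = default_knee_muscles() if muscles is None else list(muscles)
    exo = ExoParams() if exo is None else exo
    system = MuscleJointSystem(muscles, exo)
    theta0 = exo.theta_r

    def build(amp):
        ch = make_activation_profiles(pattern, t_span, rate_hz, amp,
                                      seed=seed)
        return ch, channel_to_muscle_activation(ch, muscles)

    if amplitude is None:
        amp = 0.1
        for _ in range(4):
            _, act = build(amp)
            tr = simulate(system, act, t_span, theta0, fs_out=25.0,
                          rtol=1e-5, atol=1e-7)
            rng_deg = np.degrees(tr.theta.max() - tr.theta.min())
            if abs(rng_deg - target_range_deg) < 0.02 * target_range_deg:
                break
            amp = float(np.clip(amp * target_range_deg / max(rng_deg, 1e-6),
                                1e-4, 0.95))
        amplitude = amp
    channel_fns, activations = build(amplitude)
    traj = simulate(system, activations, t_span, theta0, fs_out=fs_out,
                    rtol=rtol, atol=atol)
    rng = np.random.default_rng(seed)
    sig_th = np.radians(encoder_noise_deg)
    noisy = Trajectory(
        t=traj.t.copy(),
        theta=traj.theta + sig_th * rng.standard_normal(traj.t.size),
        theta_dot=traj.theta_dot
        + 2.0 * sig_th * rng.standard_normal(traj.t.size),
        l=traj.l.copy(), tau_h=traj.tau_h.copy(), tau_e=traj.tau_e.copy(),
        muscle_names=traj.muscle_names,
    )
    act_params = {ch: ActivationParams.from_poles(-0.35, -0.35, d=40)
                  for ch in channel_fns}
    emg = None
    mvc = None
    if with_emg:
        emg, mvc = {}, {}
        nsamp = int(round((t_span[1] - t_span[0]) * emg_fs)) + 1
        tgrid = t_span[0] + np.arange(nsamp) / emg_fs
        for i, (chname, f) in enumerate(channel_fns.items()):
            a_tr = SignalTrace(t=tgrid, values=np.clip(f(tgrid), 0, 1),
                               fs=emg_fs, channel_labels=(chname,))
            mvc[chname] = 1.0
            emg[chname] = emulate_emg(a_tr, act_params[chname],
                                      mvc=mvc[chname], snr_db=snr_db,
                                      seed=seed + 1000 + i)
    return ExperimentFixture(
        muscles=muscles, exo=exo, system=system, activations=activations,
        channel_fns=channel_fns, activation_params=act_params,
        trajectory=traj, noisy_trajectory=noisy, emg=emg, mvc=mvc,
        seed=seed, amplitude=float(amplitude),
    )


def make_benchmark_experiment(seed=0, t_span=(0.0, 8.0), rate_hz=0.25,
                              target_range_deg=90.0, flexor_boost=1.8,
                              amplitude_cycle=(1.0, 0.45), baseline=DEFAULT_TONE,
                              muscles=None, exo=None, fs_out=100.0,
                              rtol=1e-7, atol=1e-9) -> ExperimentFixture:
    """The standard optimizer-benchmark fixture: a rich calibration session.

    Two flexion-extension cycles at different burst amplitudes spanning
    roughly ``target_range_deg`` (the recording protocol covers 0-100 deg of
    knee flexion), with flexor bursts ``flexor_boost`` times the extensor
    amplitude (hamstring drive against the stronger quadriceps).  The varied
    amplitudes and wide excursion sample the force-length curves broadly,
    which is what makes the length parameters identifiable at all from a
    single session.
    """
    muscles = default_knee_muscles() if muscles is None else list(muscles)
    exo = ExoParams() if exo is None else exo
    system = MuscleJointSystem(muscles, exo)
    theta0 = exo.theta_r
    # calibrate the base burst amplitude on a single full-amplitude cycle
    probe = make_experiment(pattern="reciprocal_sine", t_span=(0.0, 1.0 / rate_hz),
                            rate_hz=rate_hz, target_range_deg=target_range_deg,
                            seed=seed, muscles=muscles, exo=exo, with_emg=False,
                            fs_out=25.0, rtol=1e-5, atol=1e-7)
    amp = probe.amplitude
    w = 2 * np.pi * rate_hz
    period = 1.0 / rate_hz
    n_cyc = len(amplitude_cycle)

    def burst(sign, boost):
        def f(t):
            t = np.asarray(t, dtype=float) - t_span[0]
            s = sign * np.sin(w * t)
            cyc = np.floor(t / period).astype(int) % n_cyc
            m = np.asarray(amplitude_cycle)[cyc]
            return np.clip(baseline + boost * amp * m * np.clip(s, 0, None) ** 2,
                           0.0, 1.0)
        return f

    channel_fns = {ch: burst(+1 if ch in _EXTENSOR_CHANNELS else -1,
                             1.0 if ch in _EXTENSOR_CHANNELS else flexor_boost)
                   for ch in DEFAULT_CHANNEL_ORDER}
    activations = channel_to_muscle_activation(channel_fns, muscles)
    traj = simulate(system, activations, t_span, theta0, fs_out=fs_out,
                    rtol=rtol, atol=atol)
    act_params = {ch: ActivationParams.from_poles(-0.35, -0.35, d=40)
                  for ch in channel_fns}
    return ExperimentFixture(
        muscles=muscles, exo=exo, system=system, activations=activations,
        channel_fns=channel_fns, activation_params=act_params,
        trajectory=traj, noisy_trajectory=None, emg=None, mvc=None,
        seed=seed, amplitude=float(amp),
    )


def make_static_record(exo: ExoParams, noise_Nm=0.0, seed=0,
                       theta_deg=None) -> StaticRecord:
    """Static stiffness protocol: holds from 120 deg to 0 in 15 deg steps.

    The hold torque is the static motion-equation torque
    tau_e = K (theta - theta_r) + tau_g sin(theta - theta_r) (no human
    torque), optionally with additive sensor noise.
    """
    if theta_deg is None:
        theta_deg = np.arange(120.0, -1.0, -15.0)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    d = th - exo.theta_r
    tau = exo.K * d + exo.tau_g * np.sin(d)
    if noise_Nm > 0:
        tau = tau + np.random.default_rng(seed).normal(0, noise_Nm, th.size)
    return StaticRecord(theta=th, tau_e=tau)


def make_dynamic_record(exo: ExoParams, duration=20.0, fs=100.0,
                        freqs_hz=(0.1, 0.25, 0.4), amp_deg=45.0,
                        center_deg=45.0, encoder_noise_deg=0.0,
                        seed=0) -> DynamicRecord:
    """Dynamic inertia/damping protocol: multi-sine sweep of the driven joint.

    The commanded trajectory superposes slow sinusoids in the 0.01-0.5 Hz
    band; the motor torque follows from the full motion equation with
    tau_h = 0.  Optional Gaussian encoder noise on the recorded angle.
    """
    t = np.arange(int(duration * fs) + 1) / fs
    th = np.full_like(t, np.radians(center_deg))
    thd = np.zeros_like(t)
    thdd = np.zeros_like(t)
    amp = np.radians(amp_deg) / len(freqs_hz)
    for i, f in enumerate(freqs_hz):
        w = 2 * np.pi * f
        ph = 0.5 * i
        th += amp * np.sin(w * t + ph)
        thd += amp * w * np.cos(w * t + ph)
        thdd += -amp * w**2 * np.sin(w * t + ph)
    d = th - exo.theta_r
    tau = exo.J * thdd + exo.B * thd + exo.K * d + exo.tau_g * np.sin(d)
    if encoder_noise_deg > 0:
        rng = np.random.default_rng(seed)
        th = th + np.radians(encoder_noise_deg) * rng.standard_normal(t.size)
    return DynamicRecord(t=t, theta=th, tau_e=tau)
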