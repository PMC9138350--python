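"""EMG preprocessing and activation dynamics.

Raw surface EMG is turned into muscle activation a(t) in four stages:

1. zero-phase 4th-order Butterworth band-pass, 20-450 Hz;
2. full-wave rectification + zero-phase 2nd-order Butterworth low-pass at
   8 Hz, normalised per channel by the maximum-voluntary-contraction (MVC)
   level and clipped to [0, 1] -> envelope e(t);
3. a damped second-order recursive filter with an electromechanical delay of
   d samples -> neural activation u(t) = alpha*e(t-d) - b1*u(t-1) - b2*u(t-2);
4. an exponential shaping nonlinearity -> muscle activation
   a(t) = (exp(A*u) - 1) / (exp(A) - 1), with shape factor -3 < A < 0.

The recursion in stage 3 must be stable (roots of z^2 + b1 z + b2 inside the
unit circle); physiological parameterisations additionally impose unit DC gain
alpha / (1 + b1 + b2) = 1 so that a sustained envelope level passes through
unchanged.  Use :meth:`ActivationParams.from_poles` to construct such sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SignalTrace",
    "ActivationParams",
    "bandpass_emg",
    "envelope_normalize",
    "neural_activation",
    "muscle_activation",
    "emg_to_activation",
]

#: band edges (Hz) of the movement-artifact band-pass stage
EMG_BAND_HZ = (20.0, 450.0)
#: cutoff (Hz) of the envelope low-pass stage
ENVELOPE_CUTOFF_HZ = 8.0


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    t : array of sample times in seconds, strictly increasing with constant
        step ``1/fs``.
    values : array, shape (n_samples,) or (n_samples, n_channels).  Units are
        mV for raw EMG and dimensionless in [0, 1] after normalisation.
    fs : sampling rate in Hz.
    channel_labels : optional muscle-group names, one per channel.
    """

    t: np.ndarray
    values: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("t must be 1-D with at least 2 samples")
        if v.shape[0] != t.size:
            raise ValueError("values and t length mismatch")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("non-finite samples in trace")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniform with step 1/fs")
        labels = tuple(self.channel_labels)
        if labels and len(labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_values(self, values: np.ndarray) -> "SignalTrace":
        return replace(self, values=np.asarray(values, dtype=float))

    @classmethod
    def from_samples(cls, values, fs, t0=0.0, channel_labels=()) -> "SignalTrace":
        values = np.asarray(values, dtype=float)
        t = t0 + np.arange(values.shape[0]) / float(fs)
        return cls(t=t, values=values, fs=float(fs), channel_labels=channel_labels)


@dataclass(frozen=True)
class ActivationParams:
    """Coefficients of the EMG-to-activation chain for one muscle.

    ``alpha`` is the gain, ``beta1``/``beta2`` the recurrence coefficients,
    ``d`` the electromechanical delay in samples and ``A`` the nonlinear
    shape factor of the activation curve.
    """

    alpha: float = field(default=None)  # type: ignore[assignment]
    beta1: float = -1.0
    beta2: float = 0.25
    d: int = 40
    A: float = -1.5

    def __post_init__(self):
        if self.alpha is None:
            # default to the unit-DC-gain value for the given recurrence
            object.__setattr__(self, "alpha", 1.0 + self.beta1 + self.beta2)
        if not (-3.0 < self.A < 0.0):
            raise ValueError(f"shape factor A={self.A} outside (-3, 0)")
        if int(self.d) != self.d or self.d < 0:
            raise ValueError("delay d must be a non-negative integer")
        object.__setattr__(self, "d", int(self.d))
        if np.max(np.abs(self.poles)) >= 1.0 - 1e-12:
            raise ValueError(
                f"unstable recursion: poles {self.poles} not inside unit circle"
            )

    @property
    def poles(self) -> np.ndarray:
        """Roots of the characteristic polynomial z^2 + beta1 z + beta2."""
        return np.roots([1.0, self.beta1, self.beta2])

    @property
    def dc_gain(self) -> float:
        return self.alpha / (1.0 + self.beta1 + self.beta2)

    @classmethod
    def from_poles(cls, c1: float, c2: float, d: int = 40, A: float = -1.5):
        """Unit-DC-gain parameter set with recursion poles at ``-c1, -c2``.

        ``beta1 = c1 + c2``, ``beta2 = c1*c2`` and ``alpha = 1 + beta1 + beta2``
        so that a constant envelope maps to the same constant activation drive.
        """
        if not (abs(c1) < 1.0 and abs(c2) < 1.0):
            raise ValueError("pole factors must satisfy |c| < 1")
        b1, b2 = c1 + c2, c1 * c2
        return cls(alpha=1.0 + b1 + b2, beta1=b1, beta2=b2, d=d, A=A)


def _butter_sos(order, wn, btype, fs):
    return _sig.butter(order, wn, btype=btype, fs=fs, output="sos")


def bandpass_emg(raw: SignalTrace) -> SignalTrace:
    """Zero-phase 4th-order Butterworth band-pass (20-450 Hz) of raw EMG."""
    lo, hi = EMG_BAND_HZ
    if raw.fs <= 2 * hi:
        raise ValueError(
            f"fs={raw.fs} Hz too low: {hi} Hz band edge at or above Nyquist"
        )
    if raw.t.size < 12:  # 3x filter order
        raise ValueError("trace too short to band-pass filter")
    sos = _butter_sos(4, (lo, hi), "bandpass", raw.fs)
    filt = _sig.sosfiltfilt(sos, raw.values, axis=0)
    return raw.with_values(filt)


def envelope_normalize(filtered: SignalTrace, mvc_level) -> SignalTrace:
    """Linear envelope e(t): rectify, low-pass at 8 Hz, divide by MVC, clip.

    ``mvc_level`` is a positive scalar or per-channel array of
    maximum-voluntary-contraction amplitudes in the same units as the trace.
    """
    mvc = np.atleast_1d(np.asarray(mvc_level, dtype=float))
    if np.any(mvc <= 0):
        raise ValueError("mvc_level must be positive")
    if mvc.size not in (1, filtered.n_channels):
        raise ValueError("mvc_level must be scalar or one per channel")
    sos = _butter_sos(2, ENVELOPE_CUTOFF_HZ, "lowpass", filtered.fs)
    env = _sig.sosfiltfilt(sos, np.abs(filtered.values), axis=0)
    if filtered.values.ndim == 1:
        env = env / mvc[0]
    else:
        env = env / mvc[np.newaxis, :]
    return filtered.with_values(np.clip(env, 0.0, 1.0))


def neural_activation(e: SignalTrace, p: ActivationParams) -> SignalTrace:
    """Neural activation u(t) = alpha e(t-d) - beta1 u(t-1) - beta2 u(t-2).

    u is taken as 0 for t < 0 and e(t-d) as 0 before the record starts.
    """
    if np.max(np.abs(p.poles)) >= 1.0:
        raise ValueError("unstable recurrence coefficients")
    v = e.values
    delayed = np.zeros_like(v)
    if p.d == 0:
        delayed[...] = v
    else:
        delayed[p.d :] = v[: v.shape[0] - p.d]
    u = _sig.lfilter([p.alpha], [1.0, p.beta1, p.beta2], delayed, axis=0)
    return e.with_values(u)


def muscle_activation(u, A: float):
    """Muscle activation a = (exp(A u) - 1) / (exp(A) - 1), -3 < A < 0.

    Maps [0, 1] onto [0, 1], strictly increasing and concave for negative A.
    Accepts a :class:`SignalTrace` or a bare array.
    """
    if not (-3.0 < A < 0.0):
        raise ValueError(f"shape factor A={A} outside (-3, 0)")
    if isinstance(u, SignalTrace):
        return u.with_values(muscle_activation(u.values, A))
    u = np.asarray(u, dtype=float)
    return np.expm1(A * u) / np.expm1(A)


def emg_to_activation(raw: SignalTrace, mvc_level, p: ActivationParams) -> SignalTrace:
    """Full chain: band-pass -> envelope/MVC -> neural -> muscle activation."""
    e = envelope_normalize(bandpass_emg(raw), mvc_level)
    u = neural_activation(e, p)
    return muscle_activation(u, p.A)
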