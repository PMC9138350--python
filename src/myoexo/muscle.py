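"""Hill-type muscle-tendon model and joint-torque summation.

Each muscle-tendon unit is a contractile element (CE) in parallel with a
passive elastic element (PE), both in series with a tendon (SE).  Lengths are
normalised: fiber length l = L / L* with L* the optimal fiber length, tendon
strain eps = (l_t - l_slack) / l_slack with l_slack the tendon slack length.

Constituent curves (all forces normalised by the maximum isometric force
F_max):

* active force-length   f_l(l)  = exp(-(l-1)^2 / gamma)            (Gaussian)
* passive force-length  f_pe(l) = (exp(k (l-1)/eps_pe) - 1)/(exp(k) - 1)
* tendon force-strain   f_se(eps): exponential toe region for
  0 < eps <= eps_toe, linear with slope k_lin above, zero when slack
* force-velocity        inverted as
  v = (0.25 + 0.75 a) V_max (f_ce - a f_l(l)) / b

Series equilibrium F_se = F_m cos(alpha_pen) closes the model: given the
muscle-tendon path length l_mt and the fiber length, the tendon length is
l_t = l_mt - L* l cos(alpha_pen), the tendon force follows from its strain,
and the CE force is whatever the equilibrium requires,
f_ce = f_se / cos(alpha_pen) - f_pe(l), clamped at zero (fibers cannot push).

Joint coupling uses a constant signed moment arm r per muscle (positive for
extensors): torque tau_h = sum_j r_j F_mt_j and path length
l_mt(theta) = l_mt0 - r (theta - theta_r).  Internal units are SI (m, N,
rad); constructors accept the cm conventions used in printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MuscleParams",
    "MuscleState",
    "active_force_length",
    "passive_force_length",
    "tendon_force_strain",
    "tendon_force_strain_deriv",
    "contraction_velocity",
    "equilibrium_fiber_force",
    "total_torque",
    "path_length",
    "isometric_equilibrium_length",
    "passive_equilibrium_length",
    "default_knee_muscles",
    "KNEE_CHANNEL_MAP",
    "TABLE_SUBJECT_CM",
]


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one Hill-type muscle-tendon unit (SI units).

    ``L_star``, ``l_slack`` and ``l_mt0`` are in meters here; use
    :meth:`from_cm` for the cm convention of printed parameter tables.
    ``moment_arm`` is signed: positive extensor, negative flexor.
    """

    name: str
    L_star: float          # optimal fiber length (m)
    F_max: float           # maximum isometric force (N)
    l_slack: float         # tendon slack length (m)
    moment_arm: float      # signed moment arm (m)
    l_mt0: float           # muscle-tendon path length at rest angle (m)
    pennation: float = 0.0
    gamma: float = 0.45    # active force-length width
    k_pe: float = 5.0      # passive exponential shape
    eps_pe: float = 0.6    # passive strain scale
    f_toe: float = 0.33    # tendon force at end of toe region
    k_toe: float = 3.0     # tendon toe exponential shape
    eps_toe: float = 0.02  # tendon strain at end of toe region
    k_lin: float = None    # tendon linear stiffness above toe (None -> C1 match)  # type: ignore[assignment]
    V_max: float = 10.0    # max contraction velocity (L*/s)
    b_fv: float = 0.25     # force-velocity shape
    channel: str = ""      # EMG channel driving this muscle

    def __post_init__(self):
        if self.k_lin is None:
            # match the toe-region end slope so the curve is C1 at eps_toe
            # (puts tendon strain at F_max near the textbook 3.3%)
            object.__setattr__(self, "k_lin", c1_tendon_slope(
                self.f_toe, self.k_toe, self.eps_toe))
        for f in ("L_star", "F_max", "l_slack", "V_max", "b_fv", "gamma",
                  "k_pe", "eps_pe", "eps_toe", "k_lin", "l_mt0"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be positive")
        if not (0.0 <= self.pennation < np.pi / 2):
            raise ValueError(f"{self.name}: pennation outside [0, pi/2)")

    @classmethod
    def from_cm(cls, name, L_star_cm, F_max, l_slack_cm, moment_arm,
                l_mt0_cm=None, **kw):
        """Build from cm lengths.

        ``l_mt0`` defaults to L* cos(pennation) + l_slack: at the rest angle
        the fiber sits at its optimal length with the tendon just taut, so
        the fully passive rest pose transmits no force (a global fixed point
        of the coupled dynamics).
        """
        L, ls = L_star_cm / 100.0, l_slack_cm / 100.0
        if l_mt0_cm is None:
            l_mt0 = L * np.cos(kw.get("pennation", 0.0)) + ls
        else:
            l_mt0 = l_mt0_cm / 100.0
        return cls(name=name, L_star=L, F_max=F_max, l_slack=ls,
                   moment_arm=moment_arm, l_mt0=l_mt0, **kw)

    def with_omega(self, L_star=None, F_max=None, l_slack=None) -> "MuscleParams":
        """Copy with the three calibrated parameters replaced (SI units)."""
        return replace(
            self,
            L_star=self.L_star if L_star is None else L_star,
            F_max=self.F_max if F_max is None else F_max,
            l_slack=self.l_slack if l_slack is None else l_slack,
        )


@dataclass(frozen=True)
class MuscleState:
    """Normalized fiber length l = L/L* and activation a in [0, 1]."""

    l: float
    activation: float

    def __post_init__(self):
        if self.l <= 0:
            raise ValueError("normalized fiber length must be positive")


# -- constituent curves ------------------------------------------------------
# All curve functions accept scalars or arrays and are complex-safe (branch
# conditions use the real part) so the dynamics rhs can be differentiated by
# complex step in tests.


def _re(x):
    return x.real if np.iscomplexobj(x) else x


def active_force_length(l, gamma):
    """Gaussian active force-length curve, peak 1 at l = 1."""
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("gamma must be positive")
    return np.exp(-((l - 1.0) ** 2) / gamma)


def passive_force_length(l, k_pe, eps_pe):
    """Exponential passive curve: 0 at l = 1, 1 at l = 1 + eps_pe."""
    if np.any(np.asarray(k_pe) <= 0) or np.any(np.asarray(eps_pe) <= 0):
        raise ValueError("passive shape constants must be positive")
    return np.expm1(k_pe * (l - 1.0) / eps_pe) / np.expm1(k_pe)


def c1_tendon_slope(f_toe=0.33, k_toe=3.0, eps_toe=0.02) -> float:
    """Linear-region tendon stiffness matching the toe-region end slope."""
    return f_toe * (k_toe / eps_toe) * np.exp(k_toe) / np.expm1(k_toe)


def tendon_force_strain(eps, f_toe=0.33, k_toe=3.0, k_lin=None,
                        eps_toe=0.02):
    """Normalized tendon force at strain eps (slack below 0, toe, linear)."""
    if k_lin is None:
        k_lin = c1_tendon_slope(f_toe, k_toe, eps_toe)
    eps = np.asarray(eps)
    toe = f_toe * np.expm1(k_toe * eps / eps_toe) / np.expm1(k_toe)
    lin = k_lin * (eps - eps_toe) + f_toe
    r = _re(eps)
    out = np.where(r > eps_toe, lin, toe)
    return np.where(r > 0.0, out, 0.0 * eps)


def tendon_force_strain_deriv(eps, f_toe=0.33, k_toe=3.0, k_lin=None,
                              eps_toe=0.02):
    """d f_se / d eps for the same branch structure."""
    if k_lin is None:
        k_lin = c1_tendon_slope(f_toe, k_toe, eps_toe)
    eps = np.asarray(eps)
    toe = f_toe * (k_toe / eps_toe) * np.exp(k_toe * eps / eps_toe) / np.expm1(k_toe)
    r = _re(eps)
    out = np.where(r > eps_toe, k_lin + 0.0 * eps, toe)
    return np.where(r > 0.0, out, 0.0 * eps)


def contraction_velocity(l, f_ce, a, params: MuscleParams):
    """Normalized fiber velocity from the inverted force-velocity relation.

    v = (0.25 + 0.75 a) V_max (f_ce - a f_l(l)) / b; positive = lengthening.
    """
    fl = active_force_length(l, params.gamma)
    return (0.25 + 0.75 * a) * params.V_max * (f_ce - a * fl) / params.b_fv


def equilibrium_fiber_force(state: MuscleState, l_mt, params: MuscleParams):
    """Series-equilibrium forces for a given fiber length and path length.

    Returns ``(f_ce, f_se, F_mt)``: normalized CE force (clamped at 0),
    normalized tendon force, and muscle-tendon force in newtons
    (``F_mt = f_se * F_max``, the force transmitted to the joint).
    """
    if _re(l_mt) <= 0:
        raise ValueError("path length must be positive")
    cosa = np.cos(params.pennation)
    l_t = l_mt - params.L_star * state.l * cosa
    eps = (l_t - params.l_slack) / params.l_slack
    f_se = tendon_force_strain(eps, params.f_toe, params.k_toe,
                               params.k_lin, params.eps_toe)
    f_pe = passive_force_length(state.l, params.k_pe, params.eps_pe)
    f_ce = f_se / cosa - f_pe
    f_ce = np.where(_re(f_ce) > 0.0, f_ce, 0.0 * f_ce)
    return float(f_ce), float(f_se), float(f_se * params.F_max)


def path_length(theta, params: MuscleParams):
    """Affine muscle-tendon path length l_mt(theta) = l_mt0 - r (theta - theta_r).

    ``theta`` is measured from the rest angle captured in ``l_mt0``; pass
    ``theta - theta_r`` when the rest angle is nonzero.
    """
    return params.l_mt0 - params.moment_arm * theta


def total_torque(states, theta_rel, muscles) -> float:
    """Joint torque tau_h = sum_j r_j F_mt_j over the configured muscle set.

    ``theta_rel`` is theta - theta_r.  Extensors (r > 0) contribute positive
    torque, flexors negative.
    """
    if len(states) != len(muscles):
        raise ValueError("state list and muscle list length mismatch")
    tau = 0.0
    for st, m in zip(states, muscles):
        _, _, F = equilibrium_fiber_force(st, path_length(theta_rel, m), m)
        tau += m.moment_arm * F
    return tau


def isometric_equilibrium_length(theta_rel, params: MuscleParams,
                                 activation=0.0, l_lo=0.2, l_hi=2.5) -> float:
    """Fiber length where the muscle is in isometric equilibrium.

    Solves f_se(eps(l)) = (f_pe(l) + a f_l(l)) cos(alpha_pen) at the given
    joint angle (relative to rest), the zero-velocity fixed point of the
    fiber dynamics at constant activation ``a``.
    """
    l_mt = path_length(theta_rel, params)
    cosa = np.cos(params.pennation)

    def g(l):
        eps = (l_mt - params.L_star * l * cosa - params.l_slack) / params.l_slack
        f_se = tendon_force_strain(eps, params.f_toe, params.k_toe,
                                   params.k_lin, params.eps_toe)
        f_m = (passive_force_length(l, params.k_pe, params.eps_pe)
               + activation * active_force_length(l, params.gamma))
        return f_se - f_m * cosa

    # widen the bracket if an extreme parameter set pushes the root outside
    glo, ghi = g(l_lo), g(l_hi)
    while glo < 0.0 and l_lo > 1e-3:
        l_lo *= 0.5
        glo = g(l_lo)
    while ghi > 0.0 and l_hi < 64.0:
        l_hi *= 2.0
        ghi = g(l_hi)
    if glo == 0.0:
        return l_lo
    if ghi == 0.0:
        return l_hi
    if glo < 0 or ghi > 0:
        raise ValueError(
            f"{params.name}: no isometric equilibrium in [{l_lo}, {l_hi}] "
            f"(path length {l_mt:.4f} m)"
        )
    return brentq(g, l_lo, l_hi, xtol=1e-14, rtol=1e-15)


def passive_equilibrium_length(theta_rel, params: MuscleParams,
                               l_lo=0.2, l_hi=2.5) -> float:
    """Fiber length where the passive muscle balances the tendon."""
    return isometric_equilibrium_length(theta_rel, params, 0.0, l_lo, l_hi)


# -- default knee model ------------------------------------------------------

#: EMG channel -> muscles driven by it (vastus group shares VM; the
#: semitendinosus shares the semimembranosus/ST channel).
KNEE_CHANNEL_MAP = {
    "RF": ("rectus_femoris",),
    "VM": ("vastus_lateralis", "vastus_medialis", "vastus_intermedius"),
    "ST": ("semimembranosus", "semitendinosus"),
    "BF": ("biceps_femoris_long", "biceps_femoris_short"),
}

#: identified subject parameters: (channel, L* cm, l_slack cm, F_max N)
TABLE_SUBJECT_CM = {
    "rectus_femoris":      ("RF", 9.8, 32.8, 850.0),
    "vastus_lateralis":    ("VM", 9.6, 12.9, 2260.0),
    "vastus_medialis":     ("VM", 10.6, 12.4, 1445.0),
    "vastus_intermedius":  ("VM", 11.5, 11.3, 1025.0),
    "semimembranosus":     ("ST", 13.4, 42.3, 1092.0),
    "semitendinosus":      ("ST", 22.3, 22.7, 315.0),
    "biceps_femoris_long": ("BF", 8.4, 31.9, 701.0),
    "biceps_femoris_short": ("BF", 9.5, 9.1, 327.0),
}

_EXTENSOR_ARM_M = 0.04
_FLEXOR_ARM_M = -0.035


def default_knee_muscles() -> list[MuscleParams]:
    """Eight knee muscle-tendon units with the identified subject parameters.

    Extensors (RF + vastus group) get +0.04 m moment arms, flexors
    (hamstrings + biceps femoris) -0.035 m.
    """
    out = []
    for name, (ch, L_cm, ls_cm, Fmax) in TABLE_SUBJECT_CM.items():
        arm = _EXTENSOR_ARM_M if ch in ("RF", "VM") else _FLEXOR_ARM_M
        out.append(MuscleParams.from_cm(name, L_cm, Fmax, ls_cm, arm, channel=ch))
    return out
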