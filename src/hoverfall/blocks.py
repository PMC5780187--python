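"""Discrete-time simulation of continuous-time LTI transfer functions.

Every dynamic element of the flight model — the wingbeat force build-up, the
passive nose-down torque during the fall, the halteres pitch-rate loop, the
visual PD controller and its derivative filter — is a small rational transfer
function in the Laplace variable ``s``.  The study simulates them at a fixed
sample period matching the camera frame rate (1/1600 s), so each block is
discretized once with the bilinear (Tustin) transform and then stepped sample
by sample inside the closed loop.

Tustin is used because it preserves DC gain exactly and maps the open left
half-plane into the unit disc, so stable blocks stay stable at any Ts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "LTIBlock",
    "discretize_lti",
    "tustin",
    "WING_FORCE_NUM",
    "WING_FORCE_DEN",
    "PASSIVE_PITCH_NUM",
    "PASSIVE_PITCH_DEN",
    "pd_tf",
    "pi_tf",
    "halteres_closed_loop_tf",
    "wing_force_response",
    "passive_pitch_response",
]

#: Wing-force transfer function C_WB(s): mass-normalised force produced by the
#: flapping wings in response to a step command, fitted to the measured
#: acceleration transient.  Second order with a zero; DC gain 1.8955, so a step
#: of |g| = 9.81 m/s^2 settles near 18.6 m/s^2 after an overshoot to ~27 m/s^2.
WING_FORCE_NUM = (0.24, 1.8955)
WING_FORCE_DEN = (0.01, 0.1, 1.0)

#: Passive body-pitch transfer function T_passive(s): the nose-down tilt of the
#: falling fly before wingbeat onset (driven by a step from 0 to -pi/2).
#: Fifth order with a double pole at the origin.
PASSIVE_PITCH_NUM = (0.001, 30.0, 0.0)
PASSIVE_PITCH_DEN = (0.0011, 0.0005, 0.01, 1.0, 0.0, 0.0)


def tustin(num, den, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-transform a continuous (num, den) pair to discrete (b, a) at
    sample rate ``fs``; an identically-zero numerator maps to the zero
    system (scipy rejects the degenerate polynomial)."""
    num = np.atleast_1d(np.asarray(num, dtype=float))
    den = np.atleast_1d(np.asarray(den, dtype=float))
    if not np.any(num):
        return np.zeros(1), np.ones(1)
    return signal.bilinear(num, den, fs=fs)


def pd_tf(kp: float, kd: float, tau: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Proportional-derivative controller with a filtered derivative,
    ``Kp + Kd*s/(tau*s + 1)``, as a (num, den) pair in descending powers of s."""
    if tau <= 0:
        raise ValueError(f"derivative filter time constant must be > 0, got {tau}")
    return (kp * tau + kd, kp), (tau, 1.0)


def pi_tf(kp: float, ki: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Proportional-integral controller ``Kp + Ki/s`` as a (num, den) pair."""
    return (kp, ki), (1.0, 0.0)


def halteres_closed_loop_tf(
    kp: float = 7.0, ki: float = 0.3, actuator_lag: float = 0.002
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Reduced closed-loop transfer function of the halteres pitch-rate loop.

    The body pitch rate is regulated by a PI controller (gains measured for the
    halteres reflex) acting through the wing-pitch actuator, modelled as a
    first-order lag with a ~2 ms time constant (one wing-stroke correction
    time).  Under unity feedback,

        CL(s) = PI*G / (1 + PI*G)
              = (Kp*s + Ki) / (tau*s^2 + (1 + Kp)*s + Ki)

    with ``G = 1/(tau*s + 1)``.  DC gain is exactly 1: constant pitch-rate
    setpoints are tracked with zero steady-state error.
    """
    return (kp, ki), (actuator_lag, 1.0 + kp, ki)


@dataclass
class LTIBlock:
    """A continuous-time rational transfer function with a discrete simulation
    state, stepped at a fixed sample period.

    The discrete difference equation (direct form II transposed) comes from the
    bilinear transform of ``num/den``.  ``step_sample`` advances one sample;
    ``simulate`` runs a whole input sequence.
    """

    num: tuple[float, ...]
    den: tuple[float, ...]
    ts: float
    b: np.ndarray = field(init=False, repr=False)
    a: np.ndarray = field(init=False, repr=False)
    _z: list[float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        num = np.trim_zeros(num, "f")
        den = np.trim_zeros(den, "f")
        if den.size == 0 or den[0] == 0.0:
            raise ValueError("denominator must have a nonzero leading coefficient")
        if num.size == 0:
            num = np.zeros(1)
        if num.size > den.size:
            raise ValueError(
                f"improper transfer function (numerator order {num.size - 1} > "
                f"denominator order {den.size - 1}); differentiate the input instead"
            )
        if self.ts <= 0:
            raise ValueError("sample period must be positive")
        b, a = tustin(num, den, 1.0 / self.ts)
        # pad so b and a share one length n; DF2T state has n-1 elements
        n = max(len(b), len(a))
        self.b = np.concatenate([b, np.zeros(n - len(b))])
        self.a = np.concatenate([a, np.zeros(n - len(a))])
        self.reset()

    @property
    def order(self) -> int:
        return len(self.a) - 1

    def reset(self) -> None:
        """Zero the internal state (block at rest)."""
        self._z = [0.0] * self.order

    def set_steady_state(self, y0: float) -> None:
        """Initialise the state so the block sits at a steady output ``y0``
        under the constant input that produces it (requires unit DC gain or
        equivalently is interpreted as input = output = y0).

        Used to hand the halteres loop a continuous pitch rate at wingbeat
        onset: the passive fall leaves the body rotating, and the loop takes
        over from that rate rather than from rest.
        """
        b, a = self.b, self.a
        z = [0.0] * self.order
        # steady DF2T state for u = y = y0: z[i] = y0 * sum_{j>i} (b[j] - a[j])
        for i in range(self.order):
            z[i] = y0 * float(np.sum(b[i + 1 :] - a[i + 1 :]))
        self._z = z

    def step_sample(self, u: float) -> float:
        """Advance one sample with input ``u``; returns the output sample."""
        b, a, z = self.b, self.a, self._z
        if not z:
            return b[0] * u
        y = b[0] * u + z[0]
        n = len(z)
        for i in range(n - 1):
            z[i] = b[i + 1] * u - a[i + 1] * y + z[i + 1]
        z[n - 1] = b[n] * u - a[n] * y
        return y

    def simulate(self, u: np.ndarray) -> np.ndarray:
        """Simulate an input sequence sampled at Ts (state carries over)."""
        u = np.asarray(u, dtype=float)
        zi = np.array(self._z)
        y, zf = signal.lfilter(self.b, self.a, u, zi=zi)
        self._z = list(zf)
        return y

    def dc_gain(self) -> float:
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if den[-1] == 0.0:
            return math.inf
        return float(num[-1] / den[-1])


def discretize_lti(num, den, ts: float) -> LTIBlock:
    """Build an :class:`LTIBlock` from continuous-time coefficients
    (descending powers of s) at sample period ``ts``."""
    return LTIBlock(tuple(num), tuple(den), ts)


def wing_force_response(t_since_onset, ts: float = 1.0 / 1600.0, g: float = 9.81):
    """Mass-normalised wing-force magnitude (m/s^2) at times after wingbeat
    onset: the response of C_WB(s) to a step of amplitude ``g``.

    Accepts a scalar or array of times; values are read off the discrete
    simulation at period ``ts`` (nearest sample at or before t) and clamped at
    zero.  At t=0 the force is zero (strictly proper system); it overshoots to
    ~27 m/s^2 near 0.13 s and settles at 1.8955*g ~ 18.6 m/s^2.
    """
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since onset must be >= 0")
    t_max = float(t.max()) if t.size else 0.0
    n = int(math.floor(t_max / ts)) + 2
    blk = discretize_lti(WING_FORCE_NUM, WING_FORCE_DEN, ts)
    y = blk.simulate(np.full(n, g))
    y = np.concatenate([[0.0], y])  # sample 0 = onset instant, force still zero
    idx = np.floor(t / ts + 1e-9).astype(int)
    out = np.maximum(y[idx], 0.0)
    return out if out.ndim else float(out)


def passive_pitch_response(t_since_release, ts: float = 1.0 / 1600.0):
    """Passive nose-down pitch (rad) of the falling fly before wingbeat onset:
    response of T_passive(s) to a step from 0 to -pi/2.

    Returns values at the requested times (scalar or array), read off the
    discrete simulation at period ``ts``.  Zero at t=0 and monotonically
    non-increasing over the fall window.
    """
    t = np.asarray(t_since_release, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since release must be >= 0")
    t_max = float(t.max()) if t.size else 0.0
    n = int(math.floor(t_max / ts)) + 2
    blk = discretize_lti(PASSIVE_PITCH_NUM, PASSIVE_PITCH_DEN, ts)
    y = blk.simulate(np.full(n, -math.pi / 2.0))
    y = np.concatenate([[0.0], y])
    idx = np.floor(t / ts + 1e-9).astype(int)
    out = y[idx]
    return out if out.ndim else float(out)
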